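{
  "@context": {
    "sg": "https://example.org/surveygraph/vocab#",
    "Protocol": "sg:Protocol",
    "Activity": "sg:Activity",
    "Item": "sg:Item",
    "ResponseFile": "sg:ResponseFile",
    "Response": "sg:Response",
    "name": {"@container": "@language", "@id": "sg:name"},
    "description": {"@container": "@language", "@id": "sg:description"},
    "prefLabel": {"@container": "@language", "@id": "sg:prefLabel"},
    "question": {"@container": "@language", "@id": "sg:question"},
    "schemaVersion": "sg:schemaVersion",
    "license": "sg:license",
    "defaultLanguage": "sg:defaultLanguage",
    "activityOrder": {"@container": "@list", "@id": "sg:activityOrder"},
    "itemOrder": {"@container": "@list", "@id": "sg:itemOrder"},
    "computeRules": {"@container": "@list", "@id": "sg:computeRules"},
    "ref": {"@type": "@id", "@id": "sg:ref"},
    "variableName": "sg:variableName",
    "required": "sg:required",
    "isVis": "sg:isVis",
    "expression": "sg:expression",
    "inputType": "sg:inputType",
    "responseOptions": "sg:responseOptions",
    "valueType": "sg:valueType",
    "choices": {"@container": "@list", "@id": "sg:choices"},
    "value": "sg:value",
    "label": {"@container": "@language", "@id": "sg:label"},
    "minValue": "sg:minValue",
    "maxValue": "sg:maxValue",
    "multipleChoice": "sg:multipleChoice",
    "missingCodes": {"@container": "@list", "@id": "sg:missingCodes"},
    "extras": "sg:extras",
    "respondent": "sg:respondent",
    "protocol": {"@type": "@id", "@id": "sg:protocol"},
    "activity": {"@type": "@id", "@id": "sg:activity"},
    "item": {"@type": "@id", "@id": "sg:item"},
    "responses": {"@container": "@list", "@id": "sg:responses"},
    "answeredAt": "sg:answeredAt"
  }
}
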