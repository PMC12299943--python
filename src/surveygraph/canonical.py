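"""Canonical JSON serialization and content digests.

Every document the package writes goes through :func:`canonical_dumps` so that
semantically identical documents are byte-identical on disk, which in turn makes
content digests stable. The digest of a document is the digest of its canonical
form with the ``@id`` key removed — the id embeds the digest, so including it
would be circular.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

DIGEST_PREFIX = "sha256-"
DIGEST_HEX_LEN = 16


def canonical_dumps(document: Any) -> str:
    """Serialize to canonical JSON: UTF-8, sorted keys, 2-space indent, LF ending."""
    return json.dumps(document, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def content_digest(document: dict) -> str:
    """Deterministic digest of a document's canonical content.

    Insensitive to key order and insignificant whitespace; the document's own
    ``@id`` is excluded so a document can carry a digest-pinned identifier.
    """
    stripped = {k: v for k, v in document.items() if k != "@id"}
    data = canonical_dumps(stripped).encode("utf-8")
    return DIGEST_PREFIX + hashlib.sha256(data).hexdigest()[:DIGEST_HEX_LEN]


def write_canonical(path, document: Any) -> None:
    text = canonical_dumps(document)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)


def read_json(path) -> Any:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
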