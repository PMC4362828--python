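"""Minting of unique, policy-conformant term URIs.

An OBO-style term URI is ``<start portion><prefix><zero-padded number>``,
e.g. ``http://purl.obolibrary.org/obo/VO_0000001``.  Numbers are assigned
incrementally from the policy's start ID, skipping any number already taken
in the target ontology — incremental assignment alone may duplicate existing
IDs, which is exactly the pitfall scanning the target ontology guards
against.  Gaps above the start are filled; numbers below the start are never
used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import AllocationError, ConfigurationError
from .manchester import _SCHEME_RE
from .settings import IdPolicy


@dataclass
class IdState:
    """Mutable allocation state: policy, taken numbers, next candidate."""

    policy: IdPolicy
    used: set[int] = field(default_factory=set)
    cursor: int = -1

    def __post_init__(self):
        if self.cursor < self.policy.start:
            self.cursor = self.policy.start


def scan_existing_ids(snapshot, policy: IdPolicy, uri_start: str) -> set[int]:
    """Numeric parts of snapshot entity URIs shaped exactly like the policy.

    Only URIs of the form ``uri_start + policy.prefix + D{policy.digits}``
    count; everything else (other prefixes, other digit widths) is ignored.
    Classes, object properties and annotation properties are all scanned —
    any entity URI can collide.
    """
    pattern = re.compile(
        re.escape(uri_start + policy.prefix) + r"(\d{%d})" % policy.digits
    )
    found: set[int] = set()
    for uri in snapshot.entity_uris:
        m = pattern.fullmatch(uri)
        if m:
            found.add(int(m.group(1)))
    return found


def allocate(state: IdState) -> str:
    """Return the next local ID string and advance the state.

    The result is ``prefix`` + the smallest eligible number >= the cursor,
    zero-padded to the policy's digit count.
    """
    limit = 10 ** state.policy.digits
    n = state.cursor
    while n < limit and n in state.used:
        n += 1
    if n >= limit:
        raise AllocationError(
            f"ID capacity exhausted: {state.policy.digits}-digit space has "
            f"0 ID(s) remaining at or above {state.cursor}"
        )
    state.used.add(n)
    state.cursor = n + 1
    return state.policy.prefix + str(n).zfill(state.policy.digits)


def mint_uri(uri_start: str, local_id: str) -> str:
    """Concatenate the URI start portion and a local ID into a term URI."""
    if not _SCHEME_RE.match(uri_start):
        raise ConfigurationError(f"URI start portion is not absolute: {uri_start!r}")
    return uri_start + local_id
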