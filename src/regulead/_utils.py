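"""Shared helpers: exceptions, logging, hashing."""
from __future__ import annotations

import hashlib
import logging
from pathlib import Path

logger = logging.getLogger("regulead")


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(ValueError):
    """A file could not be parsed in the declared dialect."""


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def child_seed(seed: int, index: int) -> int:
    """Derive a reproducible sub-seed below 2**31."""
    return (seed * 1_000_003 + index * 7919 + 17) % (2**31 - 1)
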