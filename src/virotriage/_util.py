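"""Small shared helpers."""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Any


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed percentages),
    unlike Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP) if x >= 0 else -(
        Decimal(repr(-x)).quantize(q, rounding=ROUND_HALF_UP)
    )
    return float(d)


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
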