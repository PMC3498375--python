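"""Scenario time base.

Internally every timestamp is a float count of UTC seconds since the scenario
epoch (an hour-aligned instant, so 60-min step windows coincide with UTC
hours).  Log files print ISO-8601; these helpers convert both ways.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np

#: Scenario epoch: deployments in this study system begin mid-October.
EPOCH = datetime(2009, 10, 15, 0, 0, 0, tzinfo=timezone.utc)

__all__ = ["EPOCH", "to_iso", "from_iso"]


def to_iso(seconds: float) -> str:
    """Seconds since the epoch -> ISO-8601 UTC string (ms precision when
    the instant is not on a whole second)."""
    dt = EPOCH + timedelta(seconds=float(seconds))
    if abs(seconds - round(seconds)) < 5e-4:
        return dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    return dt.strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"


def from_iso(text: str) -> float:
    """ISO-8601 UTC string -> seconds since the epoch.

    Raises ValueError for unparseable input.
    """
    t = text.strip()
    if t.endswith("Z"):
        t = t[:-1] + "+00:00"
    dt = datetime.fromisoformat(t)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return (dt - EPOCH).total_seconds()


def iso_array(seconds) -> np.ndarray:
    """Vectorised :func:`to_iso`."""
    return np.array([to_iso(s) for s in np.asarray(seconds, dtype=float)])
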