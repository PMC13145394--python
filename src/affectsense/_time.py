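"""Canonical UTC datetime64 conversion used across modules.

All comparisons are done on naive datetime64[ns] arrays in UTC; tz-aware
pandas objects are converted, never compared mixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def dt64(obj):
    """Series/array/scalar -> datetime64[ns] (scalar or ndarray), UTC-naive."""
    if isinstance(obj, pd.Series):
        s = obj
        if s.dtype == object:
            s = pd.to_datetime(s, utc=True)
        if getattr(s.dtype, "tz", None) is not None:
            s = s.dt.tz_convert("UTC").dt.tz_localize(None)
        return s.to_numpy(dtype="datetime64[ns]")
    if isinstance(obj, np.ndarray):
        if obj.dtype.kind == "M":
            return obj.astype("datetime64[ns]")
        return pd.to_datetime(pd.Series(obj), utc=True).dt.tz_localize(None).to_numpy()
    t = pd.Timestamp(obj)
    if t.tzinfo is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    return np.datetime64(t, "ns")
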