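"""Signal-detection scoring of the incidental recognition-memory task.

Sensitivity is the equal-variance d' = z(H) - z(F).  Hits and misses come
from old items that were actually rated with a button press at encoding and
belong to the scored condition; false alarms and correct rejections come
from all of the participant's new items, which carry no condition and are
therefore shared across that participant's four condition scores.  Timeout
responses are excluded from numerator and denominator (optionally treated
as "new").  Extreme rates are corrected by the standard 1/(2N) rule before
taking normal quantiles.  Per-condition d' values are additionally
mean-centered within participant to remove overall memory-capacity
differences.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ingest import CONDITIONS


def dprime(hits: int, misses: int, false_alarms: int,
           correct_rejections: int) -> float:
    """d' = z(hit rate) - z(false-alarm rate), with 1/(2N) extreme-rate correction."""
    n_signal = hits + misses
    n_noise = false_alarms + correct_rejections
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("need at least one signal and one noise trial")
    H = hits / n_signal
    F = false_alarms / n_noise
    if H in (0.0, 1.0):
        warnings.warn("extreme hit rate corrected by 1/(2N)")
        H = 1 / (2 * n_signal) if H == 0.0 else 1 - 1 / (2 * n_signal)
    if F in (0.0, 1.0):
        warnings.warn("extreme false-alarm rate corrected by 1/(2N)")
        F = 1 / (2 * n_noise) if F == 0.0 else 1 - 1 / (2 * n_noise)
    return float(norm.ppf(H) - norm.ppf(F))


def score_memory(memory: pd.DataFrame,
                 timeout_as_new: bool = False) -> pd.DataFrame:
    """Per participant x encoding-condition d' and within-participant centered d'."""
    m = memory.copy()
    if timeout_as_new:
        m.loc[m["response"] == "timeout", "response"] = "new"
    else:
        m = m[m["response"] != "timeout"]
    rows = []
    for pid, grp in m.groupby("participant_id", sort=True):
        new_items = grp[grp["status"] == "new"]
        if new_items.empty:
            raise ValueError(f"participant {pid} has no new-item responses")
        fa = int((new_items["response"] == "old").sum())
        cr = int((new_items["response"] == "new").sum())
        old = grp[(grp["status"] == "old") & grp["rated_at_encoding"]]
        for cond in CONDITIONS:
            cell = old[old["encoding_condition"] == cond]
            h = int((cell["response"] == "old").sum())
            miss = int((cell["response"] == "new").sum())
            if h + miss == 0:
                warnings.warn(f"no scored old items for {pid}/{cond}")
                continue
            rows.append({"participant_id": pid, "condition": cond,
                         "hits": h, "misses": miss, "false_alarms": fa,
                         "correct_rejections": cr,
                         "dprime": dprime(h, miss, fa, cr)})
    out = pd.DataFrame(rows)
    out["dprime_centered"] = (out["dprime"]
                              - out.groupby("participant_id")["dprime"]
                                   .transform("mean"))
    return out


def overall_dprime(memory: pd.DataFrame,
                   timeout_as_new: bool = False) -> pd.Series:
    """One d' per participant pooling old items over all conditions."""
    m = memory.copy()
    if timeout_as_new:
        m.loc[m["response"] == "timeout", "response"] = "new"
    else:
        m = m[m["response"] != "timeout"]
    vals = {}
    for pid, grp in m.groupby("participant_id", sort=True):
        new_items = grp[grp["status"] == "new"]
        old = grp[(grp["status"] == "old") & grp["rated_at_encoding"]]
        vals[pid] = dprime(int((old["response"] == "old").sum()),
                           int((old["response"] == "new").sum()),
                           int((new_items["response"] == "old").sum()),
                           int((new_items["response"] == "new").sum()))
    return pd.Series(vals, name="dprime_overall").rename_axis("participant_id")
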