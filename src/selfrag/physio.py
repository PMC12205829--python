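"""Threat-evoked skin-conductance response (SCR) analysis.

Amplitude of each response is the max-minus-min conductance over the closed
0-6 s window after a knife threat; amplitudes are square-root-transformed
before modeling (variance stabilization).  Habituation across the 12
threats of a session is captured by a 1/repetition regressor in a
random-intercept model

    sqrt_amp ~ 1 + condition + (1/repetition) + (1 | participant)

fitted with the shared profiled-REML machinery.  A per-participant
ownership-reduction index regresses sqrt amplitudes on 1/repetition alone
(pooled OLS, fixed effects only) and takes the mean residual in syncSelf
minus asyncSelf.  Descriptive epochs (-10..+20 s, linear detrend, -5..0 s
baseline subtraction) are provided for plotting only.

Events are referenced by their marker onset; no manual response-onset
picking is performed (not reproducible from data files).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import detrend

from .ingest import CONDITIONS, SAMPLING_RATE_HZ, ScrRecording, StudyDataset
from .prep import LmmFit, fit_lmm

AMPLITUDE_WINDOW_S = 6.0
EPOCH_START_S = -10.0
EPOCH_END_S = 20.0
BASELINE_WINDOW_S = (-5.0, 0.0)


def scr_amplitude(rec: ScrRecording, event) -> dict:
    """Peak-minus-trough amplitude over [onset, onset + 6 s], both ends closed."""
    onset_s, repetition = event
    i0 = int(round(onset_s * rec.sampling_rate))
    i1 = int(round((onset_s + AMPLITUDE_WINDOW_S) * rec.sampling_rate))
    if i0 < 0 or i1 >= len(rec.samples):
        raise ValueError("amplitude window exceeds trace")
    win = rec.samples[i0:i1 + 1]
    raw = float(win.max() - win.min())
    return {"participant_id": rec.participant_id, "condition": rec.condition,
            "repetition": int(repetition), "raw_amp": raw,
            "sqrt_amp": float(np.sqrt(raw))}


def scr_epoch(rec: ScrRecording, event) -> np.ndarray:
    """30 s descriptive epoch: detrended, baseline-corrected, 3001 samples."""
    onset_s, _ = event
    i0 = int(round((onset_s + EPOCH_START_S) * rec.sampling_rate))
    i1 = int(round((onset_s + EPOCH_END_S) * rec.sampling_rate))
    if i0 < 0 or i1 >= len(rec.samples):
        raise ValueError("epoch window exceeds trace")
    seg = detrend(rec.samples[i0:i1 + 1].astype(float), type="linear")
    b0 = int(round((BASELINE_WINDOW_S[0] - EPOCH_START_S) * rec.sampling_rate))
    b1 = int(round((BASELINE_WINDOW_S[1] - EPOCH_START_S) * rec.sampling_rate))
    return seg - seg[b0:b1 + 1].mean()


def extract_amplitudes(ds: StudyDataset) -> pd.DataFrame:
    """Amplitude table over every recording and threat event of a study."""
    rows = [scr_amplitude(rec, ev)
            for rec in ds.iter_recordings() for ev in rec.events]
    return pd.DataFrame(rows)


def _design(amps: pd.DataFrame, conditions=CONDITIONS):
    """Intercept + condition dummies (reference syncSelf) + 1/repetition."""
    cols = [np.ones(len(amps))]
    names = ["intercept"]
    for cond in conditions:
        if cond == "syncSelf":
            continue
        cols.append((amps["condition"] == cond).to_numpy(dtype=float))
        names.append(cond)
    cols.append(1.0 / amps["repetition"].to_numpy(dtype=float))
    names.append("inv_repetition")
    return np.column_stack(cols), names


def fit_habituation_model(amps: pd.DataFrame,
                          conditions=CONDITIONS,
                          reml: bool = True) -> LmmFit:
    """sqrt_amp ~ 1 + condition + 1/repetition + (1 | participant)."""
    if amps["participant_id"].nunique() < 2:
        raise ValueError("need >= 2 participants")
    X, names = _design(amps, conditions)
    return fit_lmm(amps["sqrt_amp"].to_numpy(dtype=float), X,
                   amps["participant_id"].to_numpy(), coef_names=names,
                   reml=reml)


def compare_repetition_codings(amps: pd.DataFrame) -> dict:
    """2 * (ML loglik with 1/n coding - with linear coding); descriptive only.

    The two codings are non-nested with equal parameter counts, so this is
    reported as a model-fit comparison, not a chi-square test.
    """
    y = amps["sqrt_amp"].to_numpy(dtype=float)
    groups = amps["participant_id"].to_numpy()
    X_inv, names = _design(amps)
    X_lin = X_inv.copy()
    X_lin[:, -1] = amps["repetition"].to_numpy(dtype=float)
    ll_inv = fit_lmm(y, X_inv, groups, coef_names=names, reml=False).loglik
    ll_lin = fit_lmm(y, X_lin, groups, coef_names=names, reml=False).loglik
    return {"loglik_inv": ll_inv, "loglik_linear": ll_lin,
            "two_loglik_diff": 2.0 * (ll_inv - ll_lin)}


def scr_reduction_index(amps: pd.DataFrame) -> pd.Series:
    """Habituation-adjusted syncSelf-minus-asyncSelf response difference.

    Pools all amplitudes in an OLS of sqrt_amp on 1/repetition, then takes
    each participant's mean residual in syncSelf minus asyncSelf.
    """
    inv = 1.0 / amps["repetition"].to_numpy(dtype=float)
    y = amps["sqrt_amp"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), inv])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = pd.Series(y - X @ beta, index=amps.index)
    out = {}
    for pid, grp in amps.groupby("participant_id", sort=True):
        means = {}
        for cond in ("syncSelf", "asyncSelf"):
            sel = grp.index[grp["condition"] == cond]
            if len(sel) == 0:
                raise ValueError(f"participant {pid} missing {cond} responses")
            means[cond] = resid[sel].mean()
        out[pid] = means["syncSelf"] - means["asyncSelf"]
    return pd.Series(out, name="scr_reduction").rename_axis("participant_id")
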