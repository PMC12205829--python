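"""End-to-end analysis: preprocessing through fragmentation, memory,
physiology, inference, and mediation, producing one machine-readable report.

The report mirrors the study's result structure: the 2x2 within-subject
ANOVA and fragmentation contrasts, cluster-count contrasts with Bayes
factors, the friend-rating semantic control, response-variance and
reaction-time controls, the recognition-memory summary, ownership
indices (questionnaire and skin conductance), the exploratory
correlations, and the single-mediator model.  Every number in the report
is the untouched output of a module-level result object.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .frag import DEFAULT_CUTOFFS, fragmentation_by_condition
from .ingest import CONDITIONS, StudyDataset, filter_rated
from .memory import overall_dprime, score_memory
from .physio import (compare_repetition_codings, extract_amplitudes,
                     fit_habituation_model, scr_reduction_index)
from .prep import illusion_scores, ownership_reduction, residualize_ratings
from .stats import (anova_2x2_within, jzs_bf01_correlation, jzs_bf01_ttest,
                    mediate, mixed_model, paired_t, spearman)


@dataclass
class AnalysisConfig:
    exclude_participants: tuple = ()
    cutoffs: tuple = DEFAULT_CUTOFFS
    n_boot: int = 10000
    seed: int = 0
    # "within": z-score each participant's asyncSelf cluster distance against
    # that participant's four condition values; "across": across participants
    zscore_mode: str = "within"

    def validate(self):
        if self.zscore_mode not in ("within", "across"):
            raise ValueError("zscore_mode must be 'within' or 'across'")
        if len(self.cutoffs) == 0 or any(c < 0 for c in self.cutoffs):
            raise ValueError("invalid cutoff grid")


class StageError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def _contrast(wide: pd.DataFrame, a: str, b: str, with_bf: bool = True) -> dict:
    sub = wide[[a, b]].dropna()
    res = paired_t(sub[a].to_numpy(), sub[b].to_numpy())
    out = {"contrast": f"{a} - {b}", **asdict(res)}
    if with_bf:
        out["bf01"] = jzs_bf01_ttest(res.t, res.n).bf01
    return out


def _wide(df: pd.DataFrame, value: str, target: str = "self") -> pd.DataFrame:
    sub = df[df["target"] == target]
    return sub.pivot_table(index="participant_id", columns="condition",
                           values=value, aggfunc="first")


def run_all(ds: StudyDataset, config: AnalysisConfig | None = None) -> dict:
    """Run the complete analysis and return the report dictionary."""
    cfg = config or AnalysisConfig()
    cfg.validate()
    report = {"provenance": {
        "input_hash": ds.content_hash(),
        "config": {**asdict(cfg),
                   "cutoffs": [float(c) for c in cfg.cutoffs],
                   "exclude_participants": list(cfg.exclude_participants)},
        "seed": cfg.seed,
        "version": __version__,
        "source": ds.meta.get("source"),
    }}

    excl = set(cfg.exclude_participants)
    keep = lambda df: df[~df["participant_id"].isin(excl)].copy()
    ratings = keep(ds.ratings)
    quest = keep(ds.questionnaires)
    mem = keep(ds.memory)
    scr = keep(ds.scr)
    scr_events = keep(ds.scr_events)
    sub = StudyDataset(ratings=ratings, questionnaires=quest, memory=mem,
                       scr=scr, scr_events=scr_events, meta=ds.meta)

    try:
        residuals = residualize_ratings(ratings)
    except Exception as e:  # noqa: BLE001
        raise StageError("prep", e)
    report["prep"] = {
        "n_rated": int(len(residuals)),
        "n_total": int(len(ratings)),
        "n_timeout_dropped": int(residuals.attrs["n_timeout_dropped"]),
        "trait_var_between": residuals.attrs["fit"].var_between,
        "trait_var_within": residuals.attrs["fit"].var_within,
    }

    try:
        fragres = fragmentation_by_condition(residuals, cfg.cutoffs,
                                             assignment=ratings)
    except Exception as e:  # noqa: BLE001
        raise StageError("frag", e)
    dist = _wide(fragres, "mean_cluster_distance").dropna()
    prop = _wide(fragres, "cluster_count_proportion").dropna()
    cells = {c: dist[c].to_numpy() for c in CONDITIONS}
    try:
        report["fragmentation"] = {
            "n_complete": int(len(dist)),
            "condition_means": {c: float(dist[c].mean()) for c in CONDITIONS},
            "anova": asdict(anova_2x2_within(cells)),
            "contrasts": [
                _contrast(dist, "asyncSelf", "syncSelf"),
                _contrast(dist, "asyncSelf", "asyncFriend"),
                _contrast(dist, "asyncSelf", "syncFriend"),
            ],
            "cluster_count_contrasts": [
                _contrast(prop, "asyncSelf", "syncSelf"),
                _contrast(prop, "asyncSelf", "asyncFriend"),
                _contrast(prop, "asyncSelf", "syncFriend"),
            ],
        }
        fdist = _wide(fragres, "mean_cluster_distance", "friend_control").dropna()
        report["friend_control"] = _contrast(fdist, "asyncSelf", "syncSelf")

        rated = filter_rated(ratings)
        selfrated = rated[rated["target"] == "self"].copy()
        selfrated["rating_f"] = selfrated["rating"].astype(float)
        var_cells = selfrated.pivot_table(index="participant_id",
                                          columns="condition",
                                          values="rating_f",
                                          aggfunc=lambda v: v.var(ddof=1)).dropna()
        rt_cells = selfrated.pivot_table(index="participant_id",
                                         columns="condition",
                                         values="reaction_time_s",
                                         aggfunc="mean").dropna()
        report["controls"] = {
            "variance": _contrast(var_cells, "asyncSelf", "syncSelf"),
            "reaction_time": _contrast(rt_cells, "asyncSelf", "syncSelf"),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("stats", e)

    try:
        scores = score_memory(mem)
        dmean = overall_dprime(mem)
        tstat = paired_t(dmean.to_numpy(), np.zeros(len(dmean)))
        report["memory"] = {
            "condition_mean_dprime": {
                c: float(scores.loc[scores["condition"] == c, "dprime"].mean())
                for c in CONDITIONS},
            "above_chance": {"t": tstat.t, "df": tstat.df,
                             "p_one_sided": tstat.p_two_sided / 2.0,
                             "n": tstat.n},
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("memory", e)

    try:
        ill = illusion_scores(quest)
        pair = ill[ill["condition"].isin(["syncSelf", "asyncSelf"])].dropna()
        X = np.column_stack([np.ones(len(pair)),
                             (pair["condition"] == "asyncSelf").to_numpy(float)])
        fit = mixed_model(pair["illusion_score"].to_numpy(float), X,
                          pair["participant_id"].to_numpy(),
                          coef_names=["intercept", "asyncSelf"])
        est, se, z, p = fit.wald("asyncSelf")
        own = ownership_reduction(quest)
        report["questionnaire"] = {
            "illusion_score_means": {
                c: float(ill.loc[ill["condition"] == c, "illusion_score"].mean())
                for c in CONDITIONS},
            "mixed_model_asyncSelf": {"estimate": est, "se": se, "z": z, "p": p},
            "ownership_reduction_mean": float(own.mean()),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("questionnaire", e)

    try:
        if len(scr):
            amps = extract_amplitudes(sub)
            hab = fit_habituation_model(amps)
            scr_red = scr_reduction_index(amps)
            report["scr"] = {
                "coefficients": dict(zip(hab.coef_names, hab.beta.tolist())),
                "asyncSelf_coefficient": float(
                    hab.beta[hab.coef_names.index("asyncSelf")]),
                "repetition_coding": compare_repetition_codings(amps),
                "reduction_index_mean": float(scr_red.mean()),
            }
        else:
            scr_red = None
            report["scr"] = None
    except Exception as e:  # noqa: BLE001
        raise StageError("physio", e)

    try:
        frag_diff = (dist["asyncSelf"] - dist["syncSelf"]).rename("frag_diff")
        if cfg.zscore_mode == "within":
            z_async = ((dist["asyncSelf"] - dist[list(CONDITIONS)].mean(axis=1))
                       / dist[list(CONDITIONS)].std(axis=1, ddof=1))
        else:
            z_async = ((dist["asyncSelf"] - dist["asyncSelf"].mean())
                       / dist["asyncSelf"].std(ddof=1))
        z_async = z_async.rename("frag_async_z")
        d_async = scores.loc[scores["condition"] == "asyncSelf"] \
            .set_index("participant_id")["dprime_centered"]

        def corr(a: pd.Series, b: pd.Series, alternative="two-sided",
                 with_bf=True):
            j = pd.concat([a, b], axis=1).dropna()
            rho, p, n = spearman(j.iloc[:, 0], j.iloc[:, 1], alternative)
            out = {"rho": rho, "p": p, "n": n, "alternative": alternative}
            if with_bf:
                out["bf01_approx"] = jzs_bf01_correlation(rho, n)
            return out

        report["correlations"] = {
            "ownership_questionnaire_vs_fragmentation": corr(own, frag_diff),
            "memory_vs_fragmentation_asyncSelf": corr(
                d_async, z_async, alternative="less", with_bf=False),
        }
        if scr_red is not None:
            report["correlations"]["ownership_scr_vs_fragmentation"] = corr(
                scr_red, frag_diff)

        med = pd.concat([own, d_async, z_async], axis=1).dropna()
        report["mediation"] = asdict(mediate(
            med.iloc[:, 0].to_numpy(), med.iloc[:, 1].to_numpy(),
            med.iloc[:, 2].to_numpy(), n_boot=cfg.n_boot, seed=cfg.seed))
    except Exception as e:  # noqa: BLE001
        raise StageError("inference", e)

    return report


def save_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")


def report_summary(report: dict) -> str:
    """Short human-readable digest of a report."""
    lines = []
    fr = report.get("fragmentation", {})
    an = fr.get("anova", {})
    lines.append(f"2x2 ANOVA interaction: F(1,{an.get('df', ['', ''])[1]}) = "
                 f"{an.get('F_interaction', float('nan')):.2f}, "
                 f"p = {an.get('p_interaction', float('nan')):.3f}")
    for c in fr.get("contrasts", []):
        lines.append(f"cluster distance {c['contrast']}: t({c['df']}) = "
                     f"{c['t']:.2f}, p = {c['p_two_sided']:.3f}, "
                     f"BF01 = {c.get('bf01', float('nan')):.2f}")
    fc = report.get("friend_control", {})
    if fc:
        lines.append(f"friend control {fc['contrast']}: t({fc['df']}) = "
                     f"{fc['t']:.2f}, p = {fc['p_two_sided']:.3f}")
    md = report.get("mediation", {})
    if md:
        lines.append(f"mediation indirect = {md['indirect_ab']:.4f}, "
                     f"Sobel z = {md['z']:.2f}, p = {md['p_sobel']:.3f}")
    return "\n".join(lines)
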