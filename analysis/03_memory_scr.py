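#!/usr/bin/env python
"""Score recognition memory and threat-evoked skin conductance.

Writes per-participant d' values (results/memory_scores.csv) and SCR
amplitudes (results/scr_amplitudes.csv), then prints the condition-mean
d' (expect an asyncSelf deficit of about 0.3) and the habituation-model
coefficients (expect a negative asyncSelf coefficient and a positive
1/repetition coefficient).
"""

from pathlib import Path

from selfrag.ingest import read_study
from selfrag.memory import score_memory
from selfrag.physio import extract_amplitudes, fit_habituation_model

ROOT = Path(__file__).resolve().parent.parent


def main():
    ds = read_study(ROOT / "scratch" / "study")
    (ROOT / "results").mkdir(exist_ok=True)

    scores = score_memory(ds.memory)
    scores.to_csv(ROOT / "results" / "memory_scores.csv", index=False)
    print("mean d' by condition:")
    print(scores.groupby("condition")["dprime"].mean().round(3).to_string())

    amps = extract_amplitudes(ds)
    amps.to_csv(ROOT / "results" / "scr_amplitudes.csv", index=False)
    fit = fit_habituation_model(amps)
    print("\nhabituation model (sqrt_amp ~ 1 + condition + 1/rep + 1|id):")
    for name, b in zip(fit.coef_names, fit.beta):
        print(f"  {name:>16s}: {b:+.4f}")


if __name__ == "__main__":
    main()
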