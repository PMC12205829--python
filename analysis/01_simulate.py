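#!/usr/bin/env python
"""Generate the synthetic study that stands in for the experiment.

Writes a complete study (ratings, questionnaires, memory responses,
skin-conductance traces) for 33 dyads at the default planted effects to
scratch/study/, and prints the bookkeeping a reader should expect:
66 participants, 120 traits each rated once about the friend and once about
the self (30 per condition), 240 memory items, 12 threat events.
"""

from pathlib import Path

from selfrag.ingest import write_study
from selfrag.synthio import SynthConfig, generate_study

OUT = Path(__file__).resolve().parent.parent / "scratch" / "study"


def main():
    cfg = SynthConfig(seed=7)
    ds = generate_study(cfg)
    write_study(ds, OUT)
    r = ds.ratings
    print(f"wrote {OUT}")
    print(f"participants: {r['participant_id'].nunique()}")
    selfr = r[r["target"] == "self"]
    print(f"self-rating rows: {len(selfr)}, "
          f"rated (non-timeout): {int(selfr['rating'].notna().sum())}")
    print(f"memory rows: {len(ds.memory)}, "
          f"threat events: {len(ds.scr_events)}")


if __name__ == "__main__":
    main()
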