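#!/usr/bin/env python
"""Score example figure-copy records under the 47-point and global/local schemes.

Three canonical cases: a perfect copy, a copy with every element present but
nothing shaped or placed correctly, and a "local-deficit" copy retaining the
global layout while dropping most local details.  Writes
results/figure_scoring_examples.tsv.
"""

from pathlib import Path

import pandas as pd

from hodomap.figures import (
    DrawingRecord,
    FeatureMark,
    default_registry,
    global_score,
    local_score,
    percent_scores,
    perfect_record,
    total_score,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    registry = default_registry()
    cases = {"perfect_copy": perfect_record(registry)}
    cases["present_without_credit"] = DrawingRecord(
        {f.id: FeatureMark(present=True) for f in registry.features}, registry
    )
    kept_local = {"arrow", "cross", "left_circle"}  # patient retains 3 of 14 details
    cases["local_deficit_copy"] = DrawingRecord(
        {
            f.id: FeatureMark(present=(f.level == "global" or f.id in kept_local))
            for f in registry.features
        },
        registry,
    )
    rows = []
    for name, rec in cases.items():
        g_pct, l_pct = percent_scores(rec)
        rows.append(
            {
                "record": name,
                "total_47": total_score(rec),
                "global_6": global_score(rec),
                "local_14": local_score(rec),
                "global_pct": round(g_pct, 1),
                "local_pct": round(l_pct, 1),
            }
        )
    frame = pd.DataFrame(rows)
    out = ROOT / "results" / "figure_scoring_examples.tsv"
    out.parent.mkdir(exist_ok=True)
    frame.to_csv(out, sep="\t", index=False)
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
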