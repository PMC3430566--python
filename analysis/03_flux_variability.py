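"""Reaction activity via FVA under the two growing conditions.

At the fixed biomass optimum each reaction's flux range is computed and
classified always / sometimes / never active; the autotrophic and
mixotrophic active sets are then compared.  Writes results/03_fva_*.tsv
and results/03_activity_comparison.tsv.
"""

from pathlib import Path

import pandas as pd

from gemflux import classify_activity, compare_condition_activity, fva, make_toy_phototroph
from gemflux.fva import active_set, class_counts
from gemflux.synth import toy_conditions

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    model, _ = make_toy_phototroph(0)
    conditions = toy_conditions()

    classes = {}
    for name in ("autotrophic", "mixotrophic"):
        result = fva(model, conditions[name])
        classes[name] = classify_activity(result)
        frame = result.to_frame()
        frame["class"] = [classes[name][r] for r in frame["reaction"]]
        frame.to_csv(RESULTS / f"03_fva_{name}.tsv", sep="\t", index=False)
        counts = class_counts(classes[name])
        print(
            f"{name}: {counts['always_active']} always / "
            f"{counts['sometimes_active']} sometimes / "
            f"{counts['never_active']} never active "
            f"(active total {len(active_set(classes[name]))} of {len(model.reactions)})"
        )

    shared, auto_only, mixo_only = compare_condition_activity(
        classes["autotrophic"], classes["mixotrophic"]
    )
    pd.DataFrame(
        [(r, "shared") for r in sorted(shared)]
        + [(r, "autotrophic_only") for r in sorted(auto_only)]
        + [(r, "mixotrophic_only") for r in sorted(mixo_only)],
        columns=["reaction", "activity"],
    ).to_csv(RESULTS / "03_activity_comparison.tsv", sep="\t", index=False)
    print(
        f"every autotrophic active reaction stays active mixotrophically "
        f"({len(auto_only)} autotrophy-only); the {len(mixo_only)} "
        f"mixotrophy-only reactions are the glucose-utilization steps: "
        f"{', '.join(sorted(mixo_only))}"
    )


if __name__ == "__main__":
    main()
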