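"""Phenotypic phase planes and robustness of the predicted growth.

Scans photon flux against bicarbonate uptake for the phototroph, segments
the plane into phases by their shadow-price signature, and runs a 1-D
photon robustness scan.  A second plane on the analytic two-substrate
fixture recovers its known phase boundary.  Writes results/05_*.tsv.
"""

from pathlib import Path

import numpy as np

from gemflux import AxisSpec, make_toy_phototroph, phenotype_phase_plane, robustness_scan, segment_phases
from gemflux.synth import SyntheticSpec, make_random_network, toy_conditions

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    model, truth = make_toy_phototroph(0)
    conditions = toy_conditions()

    grid = phenotype_phase_plane(
        model,
        conditions["autotrophic"],
        AxisSpec("EX_photon", 0.0, 1.2, 25),
        AxisSpec("EX_hco3", 0.0, 0.4, 25),
    )
    regions = segment_phases(grid)
    grid.to_frame().to_csv(RESULTS / "05_phpp_autotrophic.tsv", sep="\t", index=False)
    print(f"autotrophic phase plane: {len(regions)} regions")
    for region in regions:
        print(
            f"  region {region.region_id}: {region.label}, {region.n_points} points, "
            f"mean growth {region.mean_growth:.5f}, "
            f"shadow prices (photon {region.shadow_price_pair[0]:.4f}, "
            f"carbon {region.shadow_price_pair[1]:.4f})"
        )
    print(
        f"the growth surface equals min(carbon/{truth.extras['hco3_per_biomass']:.2f}, "
        f"photons/{truth.extras['photon_per_biomass']:.2f}): light-limited below the "
        "boundary line, carbon-limited above it"
    )

    curve = robustness_scan(
        model, conditions["autotrophic"], AxisSpec("EX_photon", 0.0, 1.0, 21)
    )
    curve.to_csv(RESULTS / "05_robustness_photon.tsv", sep="\t", index=False)
    saturation = 0.20 / truth.extras["hco3_per_biomass"]
    print(
        f"photon robustness: linear slope 1/{truth.extras['photon_per_biomass']:.2f} "
        f"until growth saturates at the carbon-limited plateau {saturation:.5f}"
    )

    two, ttruth = make_random_network(SyntheticSpec(seed=3, features=frozenset({"two_substrate"})))
    tgrid = phenotype_phase_plane(
        two, ttruth.conditions["default"],
        AxisSpec("EX_A", 0.0, 10.0, 21), AxisSpec("EX_B", 0.0, 10.0, 21),
    )
    segment_phases(tgrid)
    tgrid.to_frame().to_csv(RESULTS / "05_phpp_two_substrate.tsv", sep="\t", index=False)
    ca, cb = ttruth.extras["cost_a"], ttruth.extras["cost_b"]
    err = float(
        np.abs(
            tgrid.growth
            - np.minimum(tgrid.axis_x.values[None, :] / ca, tgrid.axis_y.values[:, None] / cb)
        ).max()
    )
    print(
        f"two-substrate fixture: surface matches min(uA/{ca:g}, uB/{cb:g}) to "
        f"{err:.1e}; the phase boundary is the line uB = ({cb:g}/{ca:g})·uA"
    )


if __name__ == "__main__":
    main()
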