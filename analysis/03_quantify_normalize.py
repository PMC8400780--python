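"""Render PRM chromatograms, integrate isomer peaks, normalize per site.

Re-generates the seed-0 cohort (deterministic), renders each patient's
fragment traces, runs the EIC quantifier over all 72 isomer entries, and
normalizes peak areas within each glycosylation site. Reports how well the
full chain recovers the generator's true relative abundances.
"""

from pathlib import Path

from hpglyco import (
    CohortConfig,
    build_quant_table,
    build_target_list,
    generate_cohort,
    normalize_by_site,
    render_chromatograms,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = CohortConfig(seed=SEED)
    targets = build_target_list()
    dataset = generate_cohort(config, targets)
    render_chromatograms(dataset, config)
    qt = build_quant_table(dataset.chromatograms, targets)
    qt.areas.to_csv(OUT / "quant_table.csv")
    rel = normalize_by_site(qt)
    rel.values.to_csv(OUT / "relative_abundance.csv")

    err = (rel.values - dataset.true_abundances).abs() / dataset.true_abundances
    print(f"quant table: {qt.areas.shape[0]} patients x {qt.areas.shape[1]} isomer entries")
    print(
        "per-entry recovery of generator truth: "
        f"median {err.stack().median():.2%}, max {err.max().max():.2%} relative error"
    )
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
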