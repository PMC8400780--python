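"""Build the packaged PRM transition list and summarize site microheterogeneity.

Constructs one target per isomer entry of the packaged haptoglobin
glycoform table (precursor m/z, six quantifier Y-ion fragments, expected
retention time), writes it to results/transition_list.csv, and reports the
per-site bookkeeping and the cross-site composition overlaps.
"""

from collections import Counter
from pathlib import Path

from hpglyco import build_target_list, site_overlap_counts
from hpglyco.io import write_transition_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    targets = build_target_list()
    write_transition_csv(targets, OUT / "transition_list.csv")

    entries = Counter(t.site.site_id for t in targets)
    forms = Counter({s: len({t.composition for t in targets if t.site.site_id == s}) for s in entries})
    print(f"{len(targets)} isomer entries over {sum(forms.values())} glycoforms")
    for site in sorted(entries):
        print(f"  {site}: {entries[site]} isomer entries, {forms[site]} glycoforms")
    print("cross-site composition overlaps (distinct compositions):")
    for sites, n in site_overlap_counts(targets).items():
        print(f"  {' ∩ '.join(sites)}: {n}")
    print(f"transition list written to {OUT / 'transition_list.csv'}")


if __name__ == "__main__":
    main()
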