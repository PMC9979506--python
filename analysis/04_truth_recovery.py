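"""Compare the scan's candidate regions with the simulator's ground truth.

For each simulated selection scenario, checks whether a candidate region
covers the selected locus (+-250 kb) and whether its assigned category
matches the simulated truth; neutral-chromosome regions count as false
positives.

Writes results/truth_recovery.tsv.
"""

from pathlib import Path

import pandas as pd

from driftscan import pipeline
from driftscan.regions import regions_from_frame

BASE = Path(__file__).resolve().parent.parent / "results"
EXPECTED = {"line_d": {"LWD"}, "line_s": {"LWS"}, "div": {"div"},
            "conv": {"conv", "conv(LWD)", "conv(LWS)"}}


def main() -> None:
    truth = pd.read_csv(BASE / "sim" / "truth.tsv", sep="\t",
                        dtype={"chrom": str})
    regions = regions_from_frame(
        pd.read_csv(BASE / "scan" / "regions.tsv", sep="\t",
                    dtype={"chrom": str}))
    rows = []
    used = set()
    for _, sc in truth.iterrows():
        hit = None
        for i, r in enumerate(regions):
            if (r.chrom == sc["chrom"] and r.start_bp <= sc["pos"] + 250_000
                    and r.end_bp >= sc["pos"] - 250_000):
                hit = (i, r)
                break
        if hit is None:
            rows.append({"chrom": sc["chrom"], "label": sc["label"],
                         "detected": False, "category": "",
                         "category_ok": False})
        else:
            used.add(hit[0])
            cat = hit[1].category or "unresolved"
            rows.append({"chrom": sc["chrom"], "label": sc["label"],
                         "detected": True, "category": cat,
                         "category_ok": cat in EXPECTED[sc["label"]]})
    out = pd.DataFrame(rows)
    out.to_csv(BASE / "truth_recovery.tsv", sep="\t", index=False)
    print(out.to_string(index=False))
    fp = [r.id for i, r in enumerate(regions) if i not in used]
    print(f"detected {int(out['detected'].sum())}/{len(out)} scenarios; "
          f"category correct for {int(out['category_ok'].sum())} of the "
          f"detected; {len(fp)} region(s) not matching any scenario: {fp}")


if __name__ == "__main__":
    main()
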