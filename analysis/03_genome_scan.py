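"""Genome scan for recent selection on the simulated design.

Runs the three whole-genome tests — hapFLK between the two modern lines
(ancestral sample as outgroup for the tree), and the temporal Wright-Fisher
HMM test of each line against the ancestral sample with local-score
segmentation — then merges the per-test segments into named candidate
regions and classifies each into a selection scenario.

Writes results/scan/: flk.tsv, hapflk.tsv, tlwd.tsv, tlws.tsv, regions.tsv.
"""

import time
from pathlib import Path

from driftscan import genio, pipeline
from driftscan.regions import regions_to_frame

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "sim"


def main() -> None:
    g = genio.read_vcf(SIM / "genotypes.vcf", SIM / "samples.tsv")
    # nfit reduced from the default 10 to keep this driver quick; the
    # statistic is an average over EM restarts either way
    cfg = pipeline.PipelineConfig(nfit=3, seed=11)
    t0 = time.time()
    res = pipeline.run_scan(g, cfg, outdir=BASE / "scan")
    frame = regions_to_frame(res["regions"])
    print(f"scan finished in {time.time() - t0:.0f}s; "
          f"{len(frame)} candidate regions:")
    if len(frame):
        print(frame[["id", "chrom", "start_mb", "end_mb", "length_kb",
                     "tests", "category"]].to_string(index=False))
    print(f"tables under {BASE/'scan'}")


if __name__ == "__main__":
    main()
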