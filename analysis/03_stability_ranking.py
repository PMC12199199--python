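"""Rank candidate references by expression stability in the Cq data.

Runs geNorm, NormFinder, BestKeeper and the comparative Delta-Ct method
on the simulated RT-qPCR table and aggregates them into a comprehensive
ranking (geometric mean of the four method ranks).  Also reports geNorm's
pairwise-variation statistic V(n/n+1) for choosing how many references
to combine.
"""

import argparse
from pathlib import Path

from evref import CqTable, genorm_v, stability_suite

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cq", type=Path, default=ROOT / "synthetic" / "cq.csv")
    parser.add_argument("--out", type=Path, default=ROOT / "stability.tsv")
    args = parser.parse_args()

    cq = CqTable.from_long_csv(args.cq)
    suite = stability_suite(cq)
    suite.index.name = "gene"
    args.out.parent.mkdir(parents=True, exist_ok=True)
    suite.to_csv(args.out, sep="\t", float_format="%.6g")

    print(suite[["delta_ct_rank", "bestkeeper_rank", "normfinder_rank",
                 "genorm_rank", "comprehensive_rank"]].to_string())
    v = genorm_v(cq.complete())
    print("\ngeNorm pairwise variation:")
    for name, val in v.items():
        print(f"  {name}: {val:.4f}")
    print(f"\nmost stable pair: {list(suite.index[:2])}")


if __name__ == "__main__":
    main()
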