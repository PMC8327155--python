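"""Amylase-style gene copy-number estimation from read depth.

Reads the simulated target/control region counts, converts read ratios to
diploid copy numbers anchored on the wolves (true CN 2), and reports each
host's estimate with its 95% interval.  True values: wolves 2, dogs 8,
ancient sample 2.
"""

from pathlib import Path

from coproscope.copynumber import estimate_copy_numbers, read_region_counts

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = read_region_counts(DATA / "region_counts.tsv")
    df = estimate_copy_numbers(counts, anchor_group="wolf",
                               anchor_copy_number=2.0, level=0.95)
    df.to_csv(OUT / "copy_numbers.tsv", sep="\t", index=False)
    print("diploid copy-number estimates (wolf-anchored, 95% CI):")
    for row in df.itertuples():
        print(f"  {row.host:10s} {row.group:8s} ratio {row.ratio:.4f}  "
              f"CN {row.copy_number:5.2f}  "
              f"[{row.cn_lo:5.2f}, {row.cn_hi:5.2f}]")
    wolves = df[df.group == "wolf"].copy_number.mean()
    print(f"anchor identity: mean wolf CN = {wolves:.6f} (exact 2 by "
          f"construction)")


if __name__ == "__main__":
    main()
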