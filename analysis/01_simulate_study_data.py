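"""Generate the synthetic study dataset: a time-calibrated bacterial tree,
a host tree over 4 wolves + 5 dogs + 1 ancient sample, a host-structured
abundance table with planted shallow-phylogeny / deep-ecology signals,
damaged ancient-DNA reads, and target/control region read counts.

Writes everything under results/data/ in the same formats the pipeline
reads back.
"""

from pathlib import Path

from coproscope import authenticity as au
from coproscope import copynumber as cn
from coproscope.diet import default_canid_diets
from coproscope.hosts import write_host_meta
from coproscope.io import write_abundance_table
from coproscope.simulate import (CommunitySimSpec, CoverageSimSpec,
                                 DamageSimSpec, simulate_coverage,
                                 simulate_reads, simulate_scenario)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 17


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = CommunitySimSpec(seed=SEED)
    tree, host_tree, table, meta = simulate_scenario(spec)
    tree.write(OUT / "tree.nwk")
    host_tree.write(OUT / "host_tree.nwk")
    write_abundance_table(table, OUT / "abundance.tsv")
    write_host_meta(default_canid_diets(meta), OUT / "hosts.tsv")

    reads = simulate_reads(DamageSimSpec(n_reads=20_000, seed=SEED + 1))
    au.write_records_tsv(reads, OUT / "reads.tsv")

    counts = simulate_coverage(CoverageSimSpec(seed=SEED + 2))
    cn.write_region_counts(counts, OUT / "region_counts.tsv")

    occ = (table.to_numpy() > 0).mean()
    print(f"bacterial tree: {tree.n_leaves} taxa, root age {tree.depth:g}")
    print(f"abundance table: {table.shape[0]} hosts x {table.shape[1]} taxa, "
          f"occupancy {occ:.2f}")
    print(f"reads: {len(reads)} with 5' damage (p0={DamageSimSpec().p0}, "
          f"lam={DamageSimSpec().lam})")
    print(f"region counts for {len(counts)} hosts "
          f"(wolves CN 2, dogs CN 8, ancient CN 2)")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
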