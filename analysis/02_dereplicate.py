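"""Dereplicate the candidate catalog by containment.

Reads results/synthetic/mges.fasta, writes the cluster table and the
non-redundant FASTA under results/catalog/.
"""

from pathlib import Path

from aquamob import io
from aquamob.catalog import MgeRecord, cluster_table, dereplicate

IN = Path("results/synthetic")
OUT = Path("results/catalog")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    seqs = io.read_fasta(IN / "mges.fasta")
    records = [MgeRecord(mge_id=k, sequence=v) for k, v in seqs.items()]
    clusters, representatives = dereplicate(records)
    table = cluster_table(clusters, representatives)
    io.write_tsv(table, OUT / "clusters.tsv")
    reps = sorted(representatives.values())
    io.write_fasta({r: seqs[r] for r in reps}, OUT / "nonredundant.fasta")
    n_multi = sum(1 for c in clusters if len(c) > 1)
    print(f"{len(records)} candidates -> {len(clusters)} non-redundant MGEs "
          f"({n_multi} clusters absorbed a contained duplicate)")


if __name__ == "__main__":
    main()
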