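"""Link MGEs to host MAGs by k-mer containment screening and CRISPR
spacer matching; summarize host associations per type and taxon.

Writes the merged link table and summaries under results/hostlink/.
"""

from pathlib import Path

import pandas as pd

from aquamob import io
from aquamob.hostlink import (kmer_screen_links, match_spacers,
                              merge_host_links, normalize_counts_by_taxon,
                              summarize_links)

SYN = Path("results/synthetic")
CAT = Path("results/catalog")
TRI = Path("results/triage")
OUT = Path("results/hostlink")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    mges = io.read_fasta(CAT / "nonredundant.fasta")
    mags = io.read_fasta(SYN / "mags.fasta")
    spacer_seqs = io.read_fasta(SYN / "spacers.fasta")
    spacer_table = io.read_tsv(SYN / "spacers.tsv")
    spacer_table["sequence"] = spacer_table["spacer_id"].map(spacer_seqs)

    kmer_links = kmer_screen_links(mges, mags)
    spacer_links = match_spacers(spacer_table, mges)
    merged = merge_host_links(kmer_links, spacer_links)
    io.write_tsv(merged, OUT / "host_links.tsv")

    taxonomy = io.read_tsv(SYN / "taxonomy.tsv")
    type_calls = io.read_tsv(TRI / "type_calls.tsv")
    summary = summarize_links(merged, taxonomy, type_calls)
    for name, frame in summary.items():
        io.write_tsv(frame, OUT / f"summary_{name}.tsv")

    labels = type_calls.set_index("mge_id")["label"]
    tax = taxonomy.set_index("mag_id")["phylum"]
    plasmid_links = merged[merged["mge_id"].map(labels) == "plasmid"]
    counts = (plasmid_links.drop_duplicates("mge_id")["mag_id"].map(tax)
              .value_counts())
    mag_cov = io.read_matrix_tsv(SYN / "coverage_mag.tsv")
    io.write_tsv(normalize_counts_by_taxon(counts, mag_cov, taxonomy),
                 OUT / "plasmids_per_phylum_normalized.tsv")

    per_type = summary["per_type"].set_index("mge_type")
    print(per_type.to_string())
    print(f"{merged['mge_id'].nunique()} of {len(mges)} non-redundant MGEs "
          "are host-associated")


if __name__ == "__main__":
    main()
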