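"""MGE -> host-MAG association.

Two in-package evidence sources plus an optional external table:

* k-mer screen: a bottom-k MinHash sketch of each MGE (k=21, 1000 hashes)
  is intersected with the full canonical-k-mer hash set of each MAG; a
  link requires >=800/1000 shared hashes and an estimated identity
  (containment**(1/k)) of >=0.99;
* CRISPR spacers: a spacer (length >25 bp) links its MAG of origin to any
  MGE containing a full-length ungapped occurrence on either strand with
  <=2 mismatches and identity (L-mm)/L >= 0.90;
* external: a precomputed host table (e.g. from an integrated phage-host
  predictor) merged as-is.

Per MGE only the best link per method is kept (k-mer: highest estimated
identity then shared hashes; spacer: fewest mismatches); links from
different methods are all retained with the method recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .minhash import MinHashSketch, SketchParams, canonical_kmer_hashes, containment, sketch
from .util import pct

logger = logging.getLogger(__name__)

LINK_COLUMNS = ["mge_id", "mag_id", "method", "shared_hashes",
                "est_identity", "spacer_id", "mismatches"]


@dataclass(frozen=True)
class SpacerParams:
    min_spacer_len: int = 26      # i.e. length > 25 bp
    max_mismatches: int = 2
    min_identity: float = 0.90
    require_full_coverage: bool = True  # always true: ungapped, full length

    def __post_init__(self):
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not self.require_full_coverage:
            raise ValueError("spacer matching is defined at 100% coverage")


def screen(mge_sketch: MinHashSketch, mag_hashes: np.ndarray, mag_id: str,
           params: SketchParams = SketchParams()) -> dict | None:
    """k-mer containment screen of one MGE sketch against one MAG."""
    shared, c, est_identity = containment(mge_sketch, mag_hashes, params.k)
    if shared >= params.min_shared and est_identity >= params.min_identity:
        return {"mge_id": mge_sketch.source_id, "mag_id": mag_id,
                "method": "kmer_screen", "shared_hashes": shared,
                "est_identity": est_identity, "spacer_id": None,
                "mismatches": None}
    return None


def kmer_screen_links(mges: dict[str, str], mags: dict[str, str],
                      params: SketchParams = SketchParams()) -> pd.DataFrame:
    """Screen every MGE sketch against every MAG k-mer pool."""
    mag_pools = {mag_id: canonical_kmer_hashes(seq, params.k)
                 for mag_id, seq in mags.items()}
    rows = []
    for mge_id in sorted(mges):
        sk = sketch(mges[mge_id], params, source_id=mge_id)
        for mag_id in sorted(mag_pools):
            hit = screen(sk, mag_pools[mag_id], mag_id, params)
            if hit is not None:
                rows.append(hit)
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _occurrences(spacer: str, mge_seq: str, max_mm: int) -> int | None:
    """Best (fewest) mismatch count of an ungapped full-length occurrence."""
    L = len(spacer)
    if L > len(mge_seq):
        return None
    target = np.frombuffer(mge_seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(target, L)
    best = None
    for probe in (spacer, spacer.translate(_COMPLEMENT)[::-1]):
        q = np.frombuffer(probe.encode(), dtype=np.uint8)
        mm = (windows != q).sum(axis=1)
        m = int(mm.min())
        if m <= max_mm and (best is None or m < best):
            best = m
    return best


def match_spacers(spacers: pd.DataFrame, mges: dict[str, str],
                  params: SpacerParams = SpacerParams()) -> pd.DataFrame:
    """Protospacer search: spacers table (spacer_id, mag_id, sequence).

    Spacers shorter than ``min_spacer_len`` are dropped (logged).  One
    link per qualifying (spacer, MGE) pair with its best mismatch count.
    """
    rows = []
    for _, sp in spacers.iterrows():
        seq = str(sp["sequence"]).upper()
        if len(seq) < params.min_spacer_len:
            logger.info("spacer %s dropped: length %d < %d",
                        sp["spacer_id"], len(seq), params.min_spacer_len)
            continue
        for mge_id in sorted(mges):
            mm = _occurrences(seq, mges[mge_id].upper(), params.max_mismatches)
            if mm is None:
                continue
            identity = (len(seq) - mm) / len(seq)
            if identity < params.min_identity:
                continue
            rows.append({"mge_id": mge_id, "mag_id": sp["mag_id"],
                         "method": "spacer", "shared_hashes": None,
                         "est_identity": identity,
                         "spacer_id": sp["spacer_id"], "mismatches": mm})
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def merge_host_links(kmer_links: pd.DataFrame, spacer_links: pd.DataFrame,
                     external_links: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-MGE assignment table keeping the top hit per method."""
    frames = []
    if len(kmer_links):
        best = (kmer_links
                .sort_values(["mge_id", "est_identity", "shared_hashes", "mag_id"],
                             ascending=[True, False, False, True])
                .groupby("mge_id", as_index=False).first())
        frames.append(best)
    if len(spacer_links):
        best = (spacer_links
                .sort_values(["mge_id", "mismatches", "mag_id"],
                             ascending=[True, True, True])
                .groupby("mge_id", as_index=False).first())
        frames.append(best)
    if external_links is not None and len(external_links):
        required = {"mge_id", "mag_id"}
        missing = required - set(external_links.columns)
        if missing:
            raise ValueError(
                f"malformed external table: missing columns {sorted(missing)}")
        for i, row in external_links.iterrows():
            if pd.isna(row["mge_id"]) or pd.isna(row["mag_id"]):
                raise ValueError(f"malformed external table at row {i}")
        ext = external_links.copy()
        ext["method"] = "external"
        for col in LINK_COLUMNS:
            if col not in ext.columns:
                ext[col] = None
        frames.append(ext[LINK_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=LINK_COLUMNS)
    merged = pd.concat(frames, ignore_index=True)[LINK_COLUMNS]
    return merged.sort_values(["mge_id", "method"]).reset_index(drop=True)


def summarize_links(assignments: pd.DataFrame, taxonomy: pd.DataFrame,
                    type_calls: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Host-association summaries: per type, per phylum, per order.

    ``taxonomy`` needs columns mag_id, phylum, order; linked MAGs missing
    from it are counted under 'unclassified' with a warning.
    """
    tax = taxonomy.set_index("mag_id")
    labels = type_calls.set_index("mge_id")["label"]
    associated = assignments.drop_duplicates("mge_id").copy()

    def _phylum(mag_id):
        if mag_id in tax.index:
            return tax.loc[mag_id, "phylum"]
        logger.warning("linked MAG %r missing taxonomy; counted as "
                       "'unclassified'", mag_id)
        return "unclassified"

    def _order(mag_id):
        return tax.loc[mag_id, "order"] if mag_id in tax.index else "unclassified"

    associated["phylum"] = associated["mag_id"].map(_phylum)
    associated["order"] = associated["mag_id"].map(_order)
    associated["label"] = associated["mge_id"].map(labels)

    per_type_rows = []
    totals = labels.value_counts()
    n_total = int(totals.sum())
    n_assoc_total = len(associated)
    per_type_rows.append({
        "mge_type": "all", "associated": n_assoc_total, "denominator": n_total,
        "percent": pct(n_assoc_total, n_total) if n_total else 0.0})
    for label in sorted(totals.index):
        n_assoc = int((associated["label"] == label).sum())
        per_type_rows.append({
            "mge_type": label, "associated": n_assoc,
            "denominator": int(totals[label]),
            "percent": pct(n_assoc, int(totals[label]))})
    per_type = pd.DataFrame(per_type_rows)

    phylum_rows = []
    for label in sorted(totals.index):
        sub = associated[associated["label"] == label]
        for phylum, count in sub["phylum"].value_counts().items():
            phylum_rows.append({
                "mge_type": label, "phylum": phylum, "count": int(count),
                "denominator": int(totals[label]),
                "percent": pct(int(count), int(totals[label]))})
    per_phylum = pd.DataFrame(
        phylum_rows, columns=["mge_type", "phylum", "count", "denominator",
                              "percent"])

    order_rows = []
    for order in sorted(set(tax["order"])):
        row = {"order": order}
        for label in sorted(totals.index):
            row[label] = bool(((associated["order"] == order) &
                               (associated["label"] == label)).any())
        order_rows.append(row)
    per_order = pd.DataFrame(order_rows)
    return {"per_type": per_type, "per_phylum": per_phylum,
            "per_order": per_order}


def normalize_counts_by_taxon(plasmid_counts: pd.Series,
                              mag_coverage: pd.DataFrame,
                              taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Plasmid counts per phylum scaled by that phylum's coverage depth.

    For each phylum and sample: value = (# distinct plasmids linked to the
    phylum) / (summed mean coverage of the phylum's MAGs in the sample).
    Phyla with zero coverage in a sample yield a missing value.
    """
    tax = taxonomy.set_index("mag_id")["phylum"]
    rows = []
    for phylum in sorted(set(tax)):
        mag_ids = [m for m in mag_coverage.index if tax.get(m) == phylum]
        count = int(plasmid_counts.get(phylum, 0))
        for sample in mag_coverage.columns:
            denom = float(mag_coverage.loc[mag_ids, sample].sum()) if mag_ids else 0.0
            value = count / denom if denom > 0 else float("nan")
            rows.append({"phylum": phylum, "sample": sample,
                         "plasmid_count": count, "coverage_sum": denom,
                         "normalized_count": value})
    return pd.DataFrame(rows)
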