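"""Seeded synthetic groundwater communities with recorded ground truth.

The generator emulates the data layout of a multi-well, two-filter-
fraction groundwater mobilome survey: well-structured MGE populations
with little cross-well sharing, log-normal plasmid lengths (median
~4.1 kb), diagnostic annotation terms planted per MGE type, host-linked
MGEs embedded verbatim (or with controlled substitutions) inside their
MAG so k-mer containment holds by construction, CRISPR spacers that are
exact or <=2-mismatch substrings of their target, per-sample rpoB counts
that modulate raw depths, and an environmental gradient that a planted
subset of MGEs follows monotonically.

Everything derives from one integer seed: identical (seed, config) gives
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .catalog import MIN_MGE_LENGTH

_BASES = np.array(list("ACGT"))

PLASMID_DIAGNOSTIC = [
    "Plasmid replication initiation protein RepA",
    "Conjugation transfer coupling protein TraG",
    "MobA family relaxase",
    "ParA family partition ATPase",
    "ParB partition protein",
    "Mobilization protein MobC",
]
PHAGE_DIAGNOSTIC = [
    "Phage major capsid protein",
    "Phage tail fiber protein",
    "Baseplate assembly protein J",
    "Head-tail connector protein",
    "Tail tape measure protein",
    "Transcription antitermination protein",
]
UMGE_DIAGNOSTIC = [
    "IS4 family transposase",
    "Integrase core domain protein",
    "Toxin-antitoxin system antitoxin HicB",
    "Site-specific recombination resolvase",
    "Chromosome segregation ATPase",
    "Excision endonuclease subunit",
]
NEUTRAL_FUNCTIONS = [
    "Hypothetical protein",
    "DNA polymerase sliding clamp",
    "ABC transporter ATP-binding protein",
    "Aminotransferase class I",
    "Cold-shock DNA-binding protein",
    "Pyruvate kinase",
    "Glutamine synthetase",
    "Elongation factor Tu",
    "NAD-dependent dehydrogenase",
    "Sulfate adenylyltransferase",
]
ENV_MARKER_FUNCTIONS = [
    "Nitric oxide dioxygenase",
    "Cobaltochelatase CobS",
    "Mercuric reductase MerA",
    "Thiosulfate sulfurtransferase",
]

_COG_LETTERS = {
    "plasmid": list("PCHKOL"),
    "phage": list("MSLKJV"),
    "uMGE": list("LXKTSD"),
}

_PHYLA = [
    ("Bacteria", "Pseudomonadota", "Alphaproteobacteria",
     ["Sphingomonadales", "Caulobacterales", "Burkholderiales"]),
    ("Bacteria", "Patescibacteria", "Paceibacteria",
     ["Paceibacterales", "Moranbacterales"]),
    ("Bacteria", "Nitrospirota", "Nitrospiria", ["Nitrospirales"]),
    ("Bacteria", "Omnitrophota", "Omnitrophia", ["Omnitrophales"]),
    ("Archaea", "Nanoarchaeota", "Nanoarchaeia", ["Woesearchaeales"]),
    ("Bacteria", "Actinobacteriota", "Actinomycetia", ["Mycobacteriales"]),
]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_wells: int = 6
    fractions: tuple = ("0.1um", "0.2um")
    replicates_per_group: int = 3
    n_plasmid: int = 20
    n_phage: int = 45
    n_umge: int = 70
    plasmid_length_log_median: float = 4100.0
    phage_length_log_median: float = 6500.0
    umge_length_log_median: float = 3000.0
    length_log_sd: float = 0.45
    cross_well_sharing_rate: float = 0.10
    n_mags: int = 30
    mag_length: int = 20000
    host_link_rate: float = 0.5
    host_mutation_rate: float = 0.0
    spacer_rate: float = 0.15
    term_planting_noise: float = 0.0
    mob_hit_rate: float = 0.18
    coverage_dispersion: float = 0.4
    rpob_range: tuple = (50, 200)
    env_gradient_strength: float = 1.0
    n_contained_copies: int = 10
    n_core_mges: int = 8
    n_env_correlated: int = 4

    def __post_init__(self):
        probs = ("cross_well_sharing_rate", "host_link_rate",
                 "host_mutation_rate", "spacer_rate", "term_planting_noise",
                 "mob_hit_rate")
        for name in probs:
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        counts = ("n_wells", "replicates_per_group", "n_plasmid", "n_phage",
                  "n_umge", "n_mags", "n_contained_copies", "n_core_mges",
                  "n_env_correlated")
        for name in counts:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lengths = ("plasmid_length_log_median", "phage_length_log_median",
                   "umge_length_log_median", "length_log_sd", "mag_length")
        for name in lengths:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_wells < 2:
            raise ValueError("n_wells must be >= 2")
        if not self.fractions:
            raise ValueError("fractions must be non-empty")
        lo, hi = self.rpob_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"rpob_range must be 0 < min <= max, "
                             f"got {self.rpob_range}")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be > 0")
        if self.env_gradient_strength < 0:
            raise ValueError("env_gradient_strength must be >= 0")
        if self.n_env_correlated > self.n_core_mges:
            raise ValueError("n_env_correlated cannot exceed n_core_mges "
                             "(environment-tracking MGEs are planted inside "
                             "the core set)")


@dataclass
class SyntheticTruth:
    true_type: dict[str, str]
    true_host: dict[str, str]
    planted_containments: list[tuple[str, str]]
    planted_spacer_hits: list[tuple[str, str, int]]
    planted_core_ids: frozenset
    planted_env_correlated_ids: frozenset
    home_well: dict[str, str] = field(default_factory=dict)
    mob_positive: frozenset = frozenset()
    wells: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "true_type": self.true_type,
            "true_host": self.true_host,
            "planted_containments": [list(t) for t in self.planted_containments],
            "planted_spacer_hits": [list(t) for t in self.planted_spacer_hits],
            "planted_core_ids": sorted(self.planted_core_ids),
            "planted_env_correlated_ids": sorted(self.planted_env_correlated_ids),
            "home_well": self.home_well,
            "mob_positive": sorted(self.mob_positive),
            "wells": self.wells,
            "samples": self.samples,
        }


@dataclass
class CoverageMatrix:
    """Depths plus the sample metadata and rpoB counts that scale them.

    ``depths`` holds the planted (rpoB-normalized) depths; ``raw()`` is
    what a mapping pipeline would report before normalization, i.e.
    depths * rpob(s) / mean(rpob) — rpoB normalization recovers
    ``depths`` exactly.
    """

    depths: pd.DataFrame
    metadata: pd.DataFrame
    rpob: pd.Series

    def raw(self) -> pd.DataFrame:
        factors = self.rpob[list(self.depths.columns)] / self.rpob[
            list(self.depths.columns)].mean()
        return self.depths * factors


@dataclass
class CommunityBundle:
    config: SimulationConfig
    mges: dict[str, str]
    mags: dict[str, str]
    annotations: pd.DataFrame
    viral: pd.DataFrame
    mob_hits: pd.DataFrame
    spacers: pd.DataFrame
    mge_coverage: CoverageMatrix
    mag_coverage_raw: pd.DataFrame
    metadata: pd.DataFrame
    rpob: pd.Series
    env: pd.DataFrame
    taxonomy: pd.DataFrame
    tpm: pd.DataFrame


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, int(length))])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.where(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _substitute(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for i in pos:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _lognormal_length(rng, median: float, sd: float) -> int:
    return max(MIN_MGE_LENGTH, int(round(rng.lognormal(np.log(median), sd))))


def _sample_table(config: SimulationConfig, wells: list[str]) -> pd.DataFrame:
    rows = []
    for well in wells:
        for frac in config.fractions:
            for rep in range(1, config.replicates_per_group + 1):
                rows.append({"sample": f"{well}_{frac}_r{rep}", "well": well,
                             "fraction": frac, "replicate": rep})
    return pd.DataFrame(rows)


def plant_coverage(truth: SyntheticTruth, config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> CoverageMatrix:
    """Depth matrix realizing the planted community structure.

    Home-well samples get high log-normal depths, other wells near-zero
    background, except the cross-well-shared fraction (one extra well),
    planted core MGEs (>1 everywhere) and the environment-tracking subset
    (monotone in the well gradient, >1 everywhere).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    meta = _sample_table(config, truth.wells)
    samples = list(meta["sample"])
    wells = truth.wells
    gradient = dict(zip(wells, np.linspace(-1, 1, len(wells))))
    disp = config.coverage_dispersion

    mge_ids = sorted(truth.true_type)
    depths = pd.DataFrame(0.0, index=mge_ids, columns=samples)
    sample_well = meta.set_index("sample")["well"]

    for mid in mge_ids:
        if mid in truth.planted_env_correlated_ids:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            for s in samples:
                g = gradient[sample_well[s]]
                base = 6.0 * np.exp(sign * 1.2 * config.env_gradient_strength * g)
                depths.loc[mid, s] = max(1.05, base * rng.lognormal(0, 0.1))
        elif mid in truth.planted_core_ids:
            for s in samples:
                depths.loc[mid, s] = max(1.5, rng.lognormal(np.log(8), disp))
        else:
            present_wells = {truth.home_well[mid]}
            if rng.random() < config.cross_well_sharing_rate and len(wells) > 1:
                others = [w for w in wells if w not in present_wells]
                present_wells.add(others[rng.integers(0, len(others))])
            for s in samples:
                if sample_well[s] in present_wells:
                    depths.loc[mid, s] = rng.lognormal(np.log(20), disp)
                elif rng.random() < 0.3:
                    depths.loc[mid, s] = rng.uniform(0.0, 0.8)

    lo, hi = config.rpob_range
    rpob = pd.Series(rng.integers(lo, hi + 1, len(samples)).astype(float),
                     index=samples, name="rpob")
    return CoverageMatrix(depths=depths, metadata=meta, rpob=rpob)


def generate_community(config: SimulationConfig,
                       out_dir: str | Path | None = None,
                       ) -> tuple[CommunityBundle, SyntheticTruth]:
    """Generate one seeded community; optionally write the fixture bundle.

    Returns the in-memory bundle and the ground truth.  When ``out_dir``
    is given, all FASTA/TSV/JSON files plus a manifest are written there.
    """
    rng = np.random.default_rng(config.seed)
    wells = [f"W{i + 1:02d}" for i in range(config.n_wells)]
    meta = _sample_table(config, wells)

    # --- MAG scaffolds and taxonomy -----------------------------------
    mag_ids = [f"mag_{i + 1:04d}" for i in range(config.n_mags)]
    mag_well = {m: wells[i % len(wells)] for i, m in enumerate(mag_ids)}
    tax_rows = []
    for i, m in enumerate(mag_ids):
        domain, phylum, klass, orders = _PHYLA[i % len(_PHYLA)]
        tax_rows.append({"mag_id": m, "domain": domain, "phylum": phylum,
                         "class": klass,
                         "order": orders[i % len(orders)]})
    taxonomy = pd.DataFrame(tax_rows)
    mag_backbones = {m: _random_seq(rng, config.mag_length) for m in mag_ids}

    # --- primary MGEs --------------------------------------------------
    true_type: dict[str, str] = {}
    mges: dict[str, str] = {}
    spec = [("pls", "plasmid", config.n_plasmid, config.plasmid_length_log_median),
            ("phg", "phage", config.n_phage, config.phage_length_log_median),
            ("umg", "uMGE", config.n_umge, config.umge_length_log_median)]
    for prefix, label, count, median in spec:
        for i in range(count):
            mid = f"{prefix}_{i + 1:04d}"
            length = _lognormal_length(rng, median, config.length_log_sd)
            mges[mid] = _random_seq(rng, length)
            true_type[mid] = label
    primary_ids = sorted(mges)

    # --- contained copies (dereplication targets) ----------------------
    planted_containments: list[tuple[str, str]] = []
    eligible_parents = [m for m in primary_ids
                        if len(mges[m]) >= int(MIN_MGE_LENGTH * 1.4)]
    for i in range(config.n_contained_copies):
        if not eligible_parents:
            break
        parent = eligible_parents[rng.integers(0, len(eligible_parents))]
        plen = len(mges[parent])
        clen = max(MIN_MGE_LENGTH, int(plen * rng.uniform(0.5, 0.9)))
        start = rng.integers(0, plen - clen + 1)
        sub = mges[parent][start:start + clen]
        if rng.random() < 0.5:
            sub = sub.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        cid = f"ctd_{i + 1:04d}"
        mges[cid] = sub
        true_type[cid] = true_type[parent]
        planted_containments.append((cid, parent))

    # --- host links: embed MGEs into MAG sequences ---------------------
    true_host: dict[str, str] = {}
    inserts: dict[str, list[str]] = {m: [] for m in mag_ids}
    for mid in primary_ids:
        if rng.random() < config.host_link_rate:
            mag = mag_ids[rng.integers(0, len(mag_ids))]
            true_host[mid] = mag
            inserts[mag].append(
                _mutate(rng, mges[mid], config.host_mutation_rate))
    mags: dict[str, str] = {}
    for m in mag_ids:
        backbone = mag_backbones[m]
        # cut the backbone once per insert so embedded MGEs stay intact
        cuts = sorted(rng.integers(0, len(backbone) + 1, len(inserts[m])))
        parts = []
        prev = 0
        for cut, ins in zip(cuts, inserts[m]):
            parts.append(backbone[prev:cut])
            parts.append(ins)
            prev = cut
        parts.append(backbone[prev:])
        mags[m] = "".join(parts)

    # --- home wells ----------------------------------------------------
    home_well: dict[str, str] = {}
    for mid in primary_ids:
        if mid in true_host:
            home_well[mid] = mag_well[true_host[mid]]
        else:
            home_well[mid] = wells[rng.integers(0, len(wells))]
    for cid, parent in planted_containments:
        home_well[cid] = home_well[parent]

    # --- planted core / environment-tracking sets ----------------------
    n_core = min(config.n_core_mges, len(primary_ids))
    core_ids = sorted(str(x) for x in
                      rng.choice(primary_ids, size=n_core, replace=False)) \
        if n_core else []
    env_ids = sorted(core_ids[:config.n_env_correlated])
    truth = SyntheticTruth(
        true_type=true_type, true_host=true_host,
        planted_containments=planted_containments,
        planted_spacer_hits=[],
        planted_core_ids=frozenset(core_ids),
        planted_env_correlated_ids=frozenset(env_ids),
        home_well=home_well, wells=wells, samples=list(meta["sample"]))

    # --- CRISPR spacers -------------------------------------------------
    spacer_rows = []
    n_spacers = int(round(config.spacer_rate * len(primary_ids)))
    linked_first = sorted(true_host) + [m for m in primary_ids
                                        if m not in true_host]
    for i in range(n_spacers):
        target = linked_first[i % len(linked_first)]
        seq = mges[target]
        L = int(rng.integers(28, 43))
        if len(seq) <= L:
            continue
        start = rng.integers(0, len(seq) - L + 1)
        proto = seq[start:start + L]
        mm = int(rng.integers(0, 3))
        spacer_seq = _substitute(rng, proto, mm) if mm else proto
        sp_id = f"sp_{i + 1:04d}"
        mag = true_host.get(target, mag_ids[rng.integers(0, len(mag_ids))])
        spacer_rows.append({"spacer_id": sp_id, "mag_id": mag,
                            "sequence": spacer_seq})
        truth.planted_spacer_hits.append((sp_id, target, mm))
    for i in range(2):  # sub-threshold decoys, dropped by the length filter
        spacer_rows.append({"spacer_id": f"sp_short_{i + 1}",
                            "mag_id": mag_ids[rng.integers(0, len(mag_ids))],
                            "sequence": _random_seq(rng, int(rng.integers(18, 25)))})
    spacers = pd.DataFrame(spacer_rows,
                           columns=["spacer_id", "mag_id", "sequence"])

    # --- annotations, viral evidence, MOB hits -------------------------
    diag = {"plasmid": PLASMID_DIAGNOSTIC, "phage": PHAGE_DIAGNOSTIC,
            "uMGE": UMGE_DIAGNOSTIC}
    ann_rows = []
    mob_rows = []
    mob_positive = set()
    viral_rows = []
    all_ids = sorted(mges)
    for mid in all_ids:
        label = true_type[mid]
        n_genes = int(rng.integers(3, 9))
        texts = []
        if rng.random() >= config.term_planting_noise:
            pool = diag[label]
            texts.append(pool[rng.integers(0, len(pool))])
        if label == "plasmid" and rng.random() < config.mob_hit_rate:
            mob_rows.append({"mge_id": mid,
                             "mob_family": ["MOBP", "MOBQ", "MOBF"][
                                 rng.integers(0, 3)]})
            mob_positive.add(mid)
        if mid in truth.planted_env_correlated_ids:
            texts.append(ENV_MARKER_FUNCTIONS[
                rng.integers(0, len(ENV_MARKER_FUNCTIONS))])
        while len(texts) < n_genes:
            texts.append(NEUTRAL_FUNCTIONS[
                rng.integers(0, len(NEUTRAL_FUNCTIONS))])
        letters = _COG_LETTERS[label]
        for j, text in enumerate(texts):
            categorized = rng.random() < 0.5
            ann_rows.append({
                "mge_id": mid, "gene_id": f"{mid}_g{j + 1}",
                "source_db": ["pfam", "cog", "kegg", "eggnog"][
                    rng.integers(0, 4)],
                "function_text": text,
                "cog_category": letters[rng.integers(0, len(letters))]
                if categorized else ""})
        viral_rows.append({"mge_id": mid,
                           "any_viral_call": bool(label == "phage"
                                                  and rng.random() < 0.7)})
    annotations = pd.DataFrame(ann_rows)
    viral = pd.DataFrame(viral_rows)
    mob_hits = pd.DataFrame(mob_rows, columns=["mge_id", "mob_family"])
    truth.mob_positive = frozenset(mob_positive)

    # --- coverage, rpoB, environment -----------------------------------
    mge_cov = plant_coverage(truth, config, rng)
    samples = list(meta["sample"])
    sample_well = meta.set_index("sample")["well"]
    gradient = dict(zip(wells, np.linspace(-1, 1, len(wells))))
    # microbial populations are broader than their MGEs: a MAG occupies
    # its home well plus possibly one or two neighbouring wells, so part
    # of the community passes prevalence-style network prefilters
    mag_depth = pd.DataFrame(0.0, index=mag_ids, columns=samples)
    for m in mag_ids:
        occupied = {mag_well[m]}
        others = [w for w in wells if w not in occupied]
        n_extra = int(rng.choice([0, 1, 2], p=[0.4, 0.4, 0.2]))
        for w in rng.choice(others, size=min(n_extra, len(others)),
                            replace=False):
            occupied.add(str(w))
        for s in samples:
            if sample_well[s] == mag_well[m]:
                mag_depth.loc[m, s] = rng.lognormal(np.log(30), 0.4)
            elif sample_well[s] in occupied:
                mag_depth.loc[m, s] = rng.lognormal(np.log(8), 0.4)
            else:
                mag_depth.loc[m, s] = rng.uniform(0.1, 1.5)
    factors = mge_cov.rpob[samples] / mge_cov.rpob[samples].mean()
    mag_cov_raw = mag_depth * factors

    g = np.array([gradient[sample_well[s]] for s in samples])
    strength = config.env_gradient_strength
    env = pd.DataFrame({
        "sample": samples,
        "pH": 7.2 + 0.8 * strength * g + rng.normal(0, 0.05, len(samples)),
        "dissolved_oxygen": 5.0 + 3.0 * strength * g
        + rng.normal(0, 0.2, len(samples)),
        "ammonium": 2.0 - 1.2 * strength * g + rng.normal(0, 0.1, len(samples)),
        "nitrate": 10.0 + 4.0 * strength * g + rng.normal(0, 0.3, len(samples)),
        "sulfate": 40.0 - 10.0 * strength * g + rng.normal(0, 1.0, len(samples)),
    })

    # --- transcripts (a few plasmid genes) ------------------------------
    tpm_genes = [r["gene_id"] for r in ann_rows
                 if r["mge_id"].startswith("pls_")][:12]
    tpm = pd.DataFrame(
        rng.lognormal(np.log(5), 1.0, (len(tpm_genes), len(samples))),
        index=tpm_genes, columns=samples)

    bundle = CommunityBundle(
        config=config, mges=mges, mags=mags, annotations=annotations,
        viral=viral, mob_hits=mob_hits, spacers=spacers,
        mge_coverage=mge_cov, mag_coverage_raw=mag_cov_raw, metadata=meta,
        rpob=mge_cov.rpob, env=env, taxonomy=taxonomy, tpm=tpm)
    if out_dir is not None:
        write_bundle(bundle, truth, out_dir)
    return bundle, truth


def write_bundle(bundle: CommunityBundle, truth: SyntheticTruth,
                 out_dir: str | Path) -> dict[str, str]:
    """Write the fixture bundle; returns the manifest mapping."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    def _path(name):
        files[name] = name
        return out / name

    io.write_fasta(dict(sorted(bundle.mges.items())), _path("mges.fasta"))
    io.write_fasta(dict(sorted(bundle.mags.items())), _path("mags.fasta"))
    io.write_tsv(bundle.annotations, _path("annotations.tsv"))
    io.write_tsv(bundle.viral, _path("viral_evidence.tsv"))
    io.write_tsv(bundle.mob_hits, _path("mob_hits.tsv"))
    spacer_seqs = {r["spacer_id"]: r["sequence"]
                   for _, r in bundle.spacers.iterrows()}
    io.write_fasta(spacer_seqs, _path("spacers.fasta"),
                   descriptions={r["spacer_id"]: f"mag={r['mag_id']}"
                                 for _, r in bundle.spacers.iterrows()})
    io.write_tsv(bundle.spacers[["spacer_id", "mag_id"]], _path("spacers.tsv"))
    io.write_matrix_tsv(bundle.mge_coverage.raw(), _path("coverage_mge.tsv"))
    io.write_matrix_tsv(bundle.mag_coverage_raw, _path("coverage_mag.tsv"))
    io.write_tsv(bundle.metadata, _path("sample_metadata.tsv"))
    io.write_tsv(bundle.rpob.rename_axis("sample").reset_index(),
                 _path("rpob.tsv"))
    io.write_tsv(bundle.env, _path("environment.tsv"))
    io.write_tsv(bundle.taxonomy, _path("taxonomy.tsv"))
    io.write_matrix_tsv(bundle.tpm, _path("tpm.tsv"))
    io.write_json(truth.to_json(), _path("truth.json"))
    manifest = {"seed": bundle.config.seed,
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(bundle.config).items()},
                "files": sorted(files)}
    io.write_json(manifest, out / "manifest.json")
    return files
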