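"""Rule-based MGE typing from protein annotations plus viral evidence.

Every catalog member receives exactly one label.  Decision order:

1. an external viral call (VirSorter2/DeepVirFinder/geNomad consensus,
   consumed as a precomputed boolean) forces ``phage`` — phages
   misclassified as plasmids by the upstream predictors are excluded here;
2. otherwise any phage-term annotation match gives ``phage``;
3. otherwise any plasmid-term match gives ``plasmid``;
4. otherwise any uMGE-term match gives ``uMGE``;
5. otherwise the element defaults to ``uMGE`` (ambiguous classification).

Term matching is case-insensitive and token-based: free text is split on
whitespace and punctuation, internal hyphens are kept so "T4-like" and
"toxin-antitoxin" are single tokens, and a term also matches a longer
hyphenated token of which it is a hyphen-boundary prefix ("head" matches
"head-tail").  Substrings inside words never match ("head" does not match
"overhead").

A plasmid additionally carries ``mobilizable=True`` when it has at least
one relaxase/MOB detection; MOB hits never change labels.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

PLASMID_TERMS = frozenset({
    "plasmid", "conjugation", "mobilization", "moba", "mobb", "mobc",
    "mobd", "mobe", "para", "parb",
})
PHAGE_TERMS = frozenset({
    "capsid", "phage", "tail", "head", "tape", "antitermination", "virus",
    "bacteriophage", "sipho", "baseplate", "t4-like", "myovir",
})
UMGE_TERMS = frozenset({
    "transposase", "transposon", "toxin-antitoxin", "excision", "integrase",
    "relaxase", "recombination", "segregation", "extrachromosomal",
    "mobilization", "partitioning",
})

LABELS = ("plasmid", "phage", "uMGE")

_TOKEN_RE = re.compile(r"[0-9a-z]+(?:-[0-9a-z]+)*")


@dataclass(frozen=True)
class TermRuleset:
    plasmid_terms: frozenset = PLASMID_TERMS
    phage_terms: frozenset = PHAGE_TERMS
    umge_terms: frozenset = UMGE_TERMS

    def __post_init__(self):
        for name in ("plasmid_terms", "phage_terms", "umge_terms"):
            terms = getattr(self, name)
            if not terms:
                raise ValueError(f"{name} must be non-empty")
            if any(t != t.lower() for t in terms):
                raise ValueError(f"{name} must be stored lowercase")


@dataclass
class MgeTypeCall:
    mge_id: str
    label: str
    matched_terms: tuple = ()
    evidence_path: tuple = ()
    mobilizable: bool = False


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def match_terms(function_text: str, terms: frozenset) -> set[str]:
    """Terms from ``terms`` matching ``function_text`` on token boundaries."""
    matched = set()
    for token in tokenize(function_text):
        for term in terms:
            if token == term or token.startswith(term + "-"):
                matched.add(term)
    return matched


def classify_one(mge_id: str, function_texts: list[str], any_viral_call: bool,
                 ruleset: TermRuleset = TermRuleset()) -> MgeTypeCall:
    """Label one MGE; deterministic and independent of annotation order."""
    blob_terms = {
        "phage": set(), "plasmid": set(), "umge": set(),
    }
    for text in function_texts:
        blob_terms["phage"] |= match_terms(text, ruleset.phage_terms)
        blob_terms["plasmid"] |= match_terms(text, ruleset.plasmid_terms)
        blob_terms["umge"] |= match_terms(text, ruleset.umge_terms)

    if any_viral_call:
        return MgeTypeCall(mge_id, "phage",
                           matched_terms=tuple(sorted(blob_terms["phage"])),
                           evidence_path=("viral_evidence",))
    if blob_terms["phage"]:
        return MgeTypeCall(mge_id, "phage",
                           matched_terms=tuple(sorted(blob_terms["phage"])),
                           evidence_path=("phage_terms",))
    if blob_terms["plasmid"]:
        return MgeTypeCall(mge_id, "plasmid",
                           matched_terms=tuple(sorted(blob_terms["plasmid"])),
                           evidence_path=("plasmid_terms",))
    if blob_terms["umge"]:
        return MgeTypeCall(mge_id, "uMGE",
                           matched_terms=tuple(sorted(blob_terms["umge"])),
                           evidence_path=("umge_terms",))
    return MgeTypeCall(mge_id, "uMGE", evidence_path=("default",))


def triage(annotations: pd.DataFrame, viral: pd.DataFrame,
           catalog_ids: list[str],
           ruleset: TermRuleset = TermRuleset()) -> list[MgeTypeCall]:
    """Label every catalog MGE.

    ``annotations`` needs columns mge_id and function_text; ``viral`` needs
    mge_id and any_viral_call (at most one row per MGE — duplicate rows
    with conflicting calls are an error).
    """
    viral_map: dict[str, bool] = {}
    for _, row in viral.iterrows():
        mid, call = row["mge_id"], bool(row["any_viral_call"])
        if mid in viral_map and viral_map[mid] != call:
            raise ValueError(f"conflicting viral-evidence rows for {mid!r}")
        viral_map[mid] = call
    texts: dict[str, list[str]] = {mid: [] for mid in catalog_ids}
    for _, row in annotations.iterrows():
        mid = row["mge_id"]
        if mid in texts:
            texts[mid].append(str(row["function_text"]))
    return [classify_one(mid, texts[mid], viral_map.get(mid, False), ruleset)
            for mid in catalog_ids]


def flag_mobilizable(calls: list[MgeTypeCall],
                     mob_hits: pd.DataFrame) -> list[MgeTypeCall]:
    """Set mobilizable=True on plasmids with >=1 MOB/relaxase hit."""
    known = {c.mge_id for c in calls}
    hit_ids = set()
    for mid in mob_hits["mge_id"]:
        if mid not in known:
            logger.warning("MOB hit on unknown mge_id %r ignored", mid)
            continue
        hit_ids.add(mid)
    out = []
    for c in calls:
        mobil = c.label == "plasmid" and c.mge_id in hit_ids
        out.append(MgeTypeCall(c.mge_id, c.label, c.matched_terms,
                               c.evidence_path, mobil))
    return out


def calls_to_table(calls: list[MgeTypeCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mge_id": c.mge_id,
        "label": c.label,
        "mobilizable": c.mobilizable,
        "matched_terms": ";".join(c.matched_terms),
        "rule_fired": ";".join(c.evidence_path),
    } for c in calls])
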