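"""Taxonomic-specificity classification of query proteins.

Each query is classified by the taxonomic distribution of its protein
homology hits: hits above the E-value cutoff are discarded, hits in the
query's own lineage (Annelida, and Mollusca as close relatives) are
ignored, and the remaining taxa decide the call — ``taxon-specific`` when a
single taxon remains, ``no_homolog`` when nothing remains (the
lineage-specific pool), ``shared`` otherwise.  Named gene-repertoire sets
(Deuterostomia-specific, Deuterostomia+Cnidaria, Cnidaria+protostome(s),
protostome-specific, lineage-specific) are assembled from the calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

TAXON_VOCABULARY = (
    "Deuterostomia",
    "Nematoda",
    "Arthropoda",
    "Platyhelminthes",
    "Cnidaria",
    "other Metazoa",
    "Choanoflagellida",
    "protists",
    "Viridiplantae",
    "Fungi",
    "other Eukaryota",
    "Prokaryotes",
    "Viruses",
    "Annelida",
    "Mollusca",
)

IGNORED_TAXA = frozenset({"Annelida", "Mollusca"})
PROTOSTOME_TAXA = frozenset({"Nematoda", "Arthropoda", "Platyhelminthes"})

CALL_SPECIFIC = "taxon-specific"
CALL_SHARED = "shared"
CALL_NO_HOMOLOG = "no_homolog"


@dataclass
class HitProfile:
    """Taxon-labelled homology hits of one query protein."""

    query_id: str
    hits: list[tuple[str, str, float]]  # (subject id, taxon, E-value)


@dataclass(frozen=True)
class SpecificityCall:
    query_id: str
    effective_taxa: frozenset[str]
    call: str           # taxon-specific | shared | no_homolog
    taxon: str | None   # set when taxon-specific


def classify(
    profile: HitProfile,
    vocab: tuple[str, ...] = TAXON_VOCABULARY,
    evalue_cutoff: float = 1e-5,
) -> SpecificityCall:
    """Classify one query from its hit profile.

    Hits with E-value above ``evalue_cutoff`` are discarded and hits in the
    ignored taxa (the query's own lineage) removed; a single remaining
    taxon makes the query specific to it, an empty set makes it
    ``no_homolog``, anything else ``shared``.
    """
    vocab_set = set(vocab)
    for _sid, taxon, ev in profile.hits:
        if taxon not in vocab_set:
            raise ValueError(f"unknown taxon label {taxon!r} for {profile.query_id}")
        if ev < 0:
            raise ValueError("negative E-value")
    effective = frozenset(
        taxon
        for _sid, taxon, ev in profile.hits
        if ev <= evalue_cutoff and taxon not in IGNORED_TAXA
    )
    if not effective:
        return SpecificityCall(profile.query_id, effective, CALL_NO_HOMOLOG, None)
    if len(effective) == 1:
        (taxon,) = effective
        return SpecificityCall(profile.query_id, effective, CALL_SPECIFIC, taxon)
    return SpecificityCall(profile.query_id, effective, CALL_SHARED, None)


SET_DEUTEROSTOMIA = "deuterostomia_specific"
SET_DEUTEROSTOMIA_CNIDARIA = "deuterostomia_cnidaria"
SET_CNIDARIA_PROTOSTOME = "cnidaria_plus_protostome"
SET_PROTOSTOME = "protostome_specific"
SET_LINEAGE = "lineage_specific"
SET_OTHER = "other"


def build_sets(calls: list[SpecificityCall]) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Assemble the named differential-gene-repertoire sets.

    * Deuterostomia-specific: effective taxa exactly {Deuterostomia};
    * Deuterostomia+Cnidaria: exactly {Deuterostomia, Cnidaria};
    * Cnidaria+protostome(s): Cnidaria plus a non-empty subset of
      {Nematoda, Arthropoda, Platyhelminthes} and nothing else;
    * protostome-specific: a non-empty subset of the protostome taxa only;
    * lineage-specific: no homolog outside the ignored lineage.

    The sets are pairwise disjoint; everything else lands in ``other``.
    """
    sets: dict[str, list[str]] = {
        SET_DEUTEROSTOMIA: [],
        SET_DEUTEROSTOMIA_CNIDARIA: [],
        SET_CNIDARIA_PROTOSTOME: [],
        SET_PROTOSTOME: [],
        SET_LINEAGE: [],
        SET_OTHER: [],
    }
    rows = []
    for call in calls:
        t = call.effective_taxa
        if call.call == CALL_NO_HOMOLOG:
            name = SET_LINEAGE
        elif t == {"Deuterostomia"}:
            name = SET_DEUTEROSTOMIA
        elif t == {"Deuterostomia", "Cnidaria"}:
            name = SET_DEUTEROSTOMIA_CNIDARIA
        elif (
            "Cnidaria" in t
            and t - {"Cnidaria"} <= PROTOSTOME_TAXA
            and t - {"Cnidaria"}
        ):
            name = SET_CNIDARIA_PROTOSTOME
        elif t and t <= PROTOSTOME_TAXA:
            name = SET_PROTOSTOME
        else:
            name = SET_OTHER
        sets[name].append(call.query_id)
        rows.append({"query": call.query_id, "set": name, "call": call.call})
    membership = pd.DataFrame(rows, columns=["query", "set", "call"])
    return sets, membership


def aggregate_by_family(
    calls: list[SpecificityCall], family_of: dict[str, str]
) -> dict[str, str]:
    """Optional aggregation of per-protein calls to families by majority
    vote on the set label (ties: alphabetical label)."""
    _, membership = build_sets(calls)
    membership = membership.assign(
        family=[family_of.get(q, q) for q in membership["query"]]
    )
    out = {}
    for fam, grp in membership.groupby("family"):
        counts = grp["set"].value_counts()
        top = counts[counts == counts.max()].index.min()
        out[fam] = top
    return out
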