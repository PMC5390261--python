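"""Protein identification acceptance pipeline.

Consumes the output abstraction of a database search: peptide-spectrum
matches (PSMs) with assigned probabilities and decoy flags.  Three stages:

1. :func:`filter_psms` — keep PSMs with probability strictly above 0.95
   (peptide-level acceptance).
2. :func:`group_proteins_parsimony` — report the minimal set of protein
   groups explaining every retained peptide; proteins with identical
   peptide evidence are merged, proteins whose evidence is a subset of
   another's are absorbed, and the cover is completed greedily.
3. :func:`accept_protein_groups` — accept groups with probability strictly
   above 0.99 and at least 2 unique peptides, then verify the decoy-based
   protein FDR (decoys/targets among retained) is at most 1%, escalating
   the probability threshold by the smallest step that achieves it.

Probability models themselves (PeptideProphet/ProteinProphet, Percolator)
are out of scope: probabilities are inputs.  A protein's probability is the
maximum PSM probability over its peptides, and a group's the maximum over
its members.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "filter_psms",
    "group_proteins_parsimony",
    "accept_protein_groups",
    "parse_mapped_accessions",
]


def parse_mapped_accessions(value) -> tuple[str, ...]:
    """Normalize the mapped_accessions cell (``;``-joined string or iterable)
    into a sorted tuple of accessions."""
    if isinstance(value, str):
        parts = [p.strip() for p in value.split(";")]
    else:
        parts = [str(p).strip() for p in value]
    parts = [p for p in parts if p]
    if not parts:
        raise ValueError("a PSM must map to at least one accession")
    return tuple(sorted(set(parts)))


def filter_psms(psms: pd.DataFrame, min_probability: float = 0.95) -> pd.DataFrame:
    """Retain exactly the PSMs with probability strictly greater than the
    cutoff; input order is preserved.  An empty table is returned empty."""
    if not 0.0 <= min_probability <= 1.0:
        raise ValueError("min_probability must lie in [0, 1]")
    if len(psms):
        p = psms["probability"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("PSM probabilities must lie in [0, 1]")
    return psms[psms["probability"] > min_probability].copy()


def group_proteins_parsimony(psms: pd.DataFrame) -> pd.DataFrame:
    """Group proteins into a greedy-minimal set of groups explaining all
    peptides.

    Proteins with identical peptide sets merge into one group (they cannot
    be differentiated by the spectra alone); a protein whose peptide set is
    a strict subset of another's is absorbed into it.  The remaining cover
    is chosen greedily — most uncovered peptides first, ties broken by more
    total peptides then lexicographically smallest lead accession — which on
    small instances coincides with the exact minimum cover.

    Returns one row per surviving group: lead_accession, member_accessions,
    peptides, unique_peptide_count (peptides explained by exactly one
    surviving group), probability (max over member PSMs), decoy (true iff
    every member is decoy-only).
    """
    pep_of: dict[str, set] = {}
    prob_of: dict[str, float] = {}
    target_of: dict[str, bool] = {}
    for _, row in psms.iterrows():
        for acc in parse_mapped_accessions(row["mapped_accessions"]):
            pep_of.setdefault(acc, set()).add(row["peptide"])
            prob_of[acc] = max(prob_of.get(acc, 0.0), float(row["probability"]))
            target_of[acc] = target_of.get(acc, False) or not bool(row["decoy"])

    if not pep_of:
        return pd.DataFrame(
            columns=[
                "lead_accession",
                "member_accessions",
                "peptides",
                "unique_peptide_count",
                "probability",
                "decoy",
            ]
        )

    # Merge indistinguishable proteins (identical peptide sets).
    by_set: dict[frozenset, list[str]] = {}
    for acc, peps in pep_of.items():
        by_set.setdefault(frozenset(peps), []).append(acc)
    groups = [
        {"members": sorted(members), "peptides": peps}
        for peps, members in by_set.items()
    ]

    # Absorb strict subsets into their (deterministically chosen) superset.
    groups.sort(key=lambda g: (-len(g["peptides"]), g["members"][0]))
    absorbed = [False] * len(groups)
    for i, gi in enumerate(groups):
        if absorbed[i]:
            continue
        for j in range(i + 1, len(groups)):
            if absorbed[j]:
                continue
            if groups[j]["peptides"] < gi["peptides"]:
                gi["members"] = sorted(set(gi["members"]) | set(groups[j]["members"]))
                absorbed[j] = True
    groups = [g for i, g in enumerate(groups) if not absorbed[i]]

    # Greedy cover over the remaining groups.
    uncovered = set().union(*(g["peptides"] for g in groups))
    chosen = []
    remaining = list(groups)
    while uncovered:
        remaining.sort(
            key=lambda g: (
                -len(g["peptides"] & uncovered),
                -len(g["peptides"]),
                g["members"][0],
            )
        )
        best = remaining.pop(0)
        if not best["peptides"] & uncovered:
            break
        chosen.append(best)
        uncovered -= best["peptides"]

    # Peptides explained by exactly one surviving group are unique evidence.
    pep_group_count: dict[str, int] = {}
    for g in chosen:
        for pep in g["peptides"]:
            pep_group_count[pep] = pep_group_count.get(pep, 0) + 1

    rows = []
    for g in sorted(chosen, key=lambda g: g["members"][0]):
        members = g["members"]
        rows.append(
            {
                "lead_accession": members[0],
                "member_accessions": ";".join(members),
                "peptides": ";".join(sorted(g["peptides"])),
                "unique_peptide_count": sum(
                    1 for pep in g["peptides"] if pep_group_count[pep] == 1
                ),
                "probability": max(prob_of[m] for m in members),
                "decoy": not any(target_of[m] for m in members),
            }
        )
    return pd.DataFrame(rows)


def accept_protein_groups(
    groups: pd.DataFrame,
    min_protein_probability: float = 0.99,
    min_unique_peptides: int = 2,
    max_fdr: float = 0.01,
) -> pd.DataFrame:
    """Accept groups passing the probability and unique-peptide gates while
    keeping the decoy-estimated protein FDR within ``max_fdr``.

    The FDR estimator is decoys/targets among retained groups.  If the fixed
    thresholds leave the FDR above ``max_fdr``, the probability threshold is
    raised to the smallest retained-group probability that restores the
    bound.  Decoy groups are removed from the returned table.
    """
    if len(groups) and not (~groups["decoy"]).any():
        raise ValueError("all retained groups are decoys; FDR is uninterpretable")

    def retained(threshold: float) -> pd.DataFrame:
        return groups[
            (groups["probability"] > threshold)
            & (groups["unique_peptide_count"] >= min_unique_peptides)
        ]

    kept = retained(min_protein_probability)

    def fdr(frame: pd.DataFrame) -> float:
        n_targets = int((~frame["decoy"]).sum())
        n_decoys = int(frame["decoy"].sum())
        if n_targets == 0:
            return 0.0 if n_decoys == 0 else float("inf")
        return n_decoys / n_targets

    if fdr(kept) > max_fdr:
        # Escalate: each retained probability is a candidate threshold; the
        # smallest one restoring the bound wins.
        candidates = sorted(set(kept["probability"]))
        for threshold in candidates:
            kept = retained(threshold)
            if fdr(kept) <= max_fdr:
                break
        else:
            kept = kept.iloc[0:0]
    return kept[~kept["decoy"]].reset_index(drop=True)
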