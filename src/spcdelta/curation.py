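"""Post-testing protein selection: contaminant and annotation-quality filters.

After differential calling, the retained lists are curated with a fixed,
auditable sequence of exclusion rules:

1. ``not_significant`` — proteins not called differential.
2. ``keratin`` — ubiquitous sample-handling contaminants.
3. ``no_accession`` — entries with no reported accession (unidentifiable).
4. ``fragment`` — peptide-fragment entries without a reliable function.
5. ``uncharacterized`` — putative uncharacterized proteins.
6. ``cdna_like`` — cDNA-like database entries.
7. ``skeletal_muscle`` — xenograft-only: skeletal-muscle proteins, likely
   contamination introduced when excising the tumor from the host animal.

Each exclusion is attributed to the *first* matching rule in this order, so
the per-rule counts plus the retained count always reconcile with the input
count.  Keyword matching is case-insensitive on the description field (the
skeletal-muscle keyword is deliberately narrow — "skeletal muscle" in the
description — because muscle-associated gene names such as tropomyosins
occur as genuine signal and must not trigger exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CurationRule",
    "CurationReport",
    "default_rules",
    "apply_exclusion_rules",
    "curation_report",
]

RULE_ORDER = (
    "not_significant",
    "keratin",
    "no_accession",
    "fragment",
    "uncharacterized",
    "cdna_like",
    "skeletal_muscle",
)


@dataclass
class CurationRule:
    """One keyword exclusion rule.

    ``keywords`` are matched case-insensitively against the description;
    ``gene_prefixes`` (if any) against the gene symbol.  ``applies_to``
    restricts the rule to given compartments (None = all compartments).
    """

    name: str
    keywords: tuple[str, ...] = ()
    gene_prefixes: tuple[str, ...] = ()
    applies_to: tuple[str, ...] | None = None

    def matches(self, description: str, gene_symbol: str, reported_accession: str, compartment: str) -> bool:
        if self.applies_to is not None and compartment not in self.applies_to:
            return False
        if self.name == "no_accession":
            return reported_accession.strip() == ""
        desc = description.lower()
        if any(kw.lower() in desc for kw in self.keywords):
            return True
        gene = gene_symbol.upper()
        return any(gene.startswith(pfx.upper()) for pfx in self.gene_prefixes)


def default_rules() -> list[CurationRule]:
    """The keyword rules in their fixed attribution order (the significance
    gate is applied before any of them)."""
    return [
        CurationRule("keratin", keywords=("keratin",), gene_prefixes=("KRT",)),
        CurationRule("no_accession"),
        CurationRule("fragment", keywords=("(fragment)", "fragment")),
        CurationRule("uncharacterized", keywords=("putative uncharacter",)),
        CurationRule("cdna_like", keywords=("cdna",)),
        CurationRule("skeletal_muscle", keywords=("skeletal muscle",), applies_to=("xenograft",)),
    ]


@dataclass
class CurationReport:
    """Per-rule exclusion ledger: accession lists, counts, retained count."""

    excluded: dict = field(default_factory=dict)
    retained_count: int = 0
    input_count: int = 0

    def counts(self) -> dict:
        return {rule: len(accs) for rule, accs in self.excluded.items()}

    def total_excluded(self) -> int:
        return sum(len(accs) for accs in self.excluded.values())


def apply_exclusion_rules(
    results: pd.DataFrame,
    proteins: pd.DataFrame,
    rules: list[CurationRule] | None = None,
) -> tuple[pd.DataFrame, CurationReport]:
    """Filter a called differential-results table; returns (retained, report).

    ``results`` must carry accession, compartment and call columns;
    ``proteins`` supplies description/gene metadata per accession.  A tested
    protein missing from the metadata is an error naming the accession.
    """
    if rules is None:
        rules = default_rules()
    known = {r.name for r in rules} | {"not_significant"}
    unknown = known - set(RULE_ORDER)
    if unknown:
        raise ValueError(f"unknown curation rule(s): {sorted(unknown)}")

    meta = proteins.set_index("accession")
    report = CurationReport(
        excluded={"not_significant": []} | {r.name: [] for r in rules},
        input_count=len(results),
    )
    keep_rows = []
    for _, row in results.iterrows():
        acc = row["accession"]
        if acc not in meta.index:
            raise ValueError(f"no protein metadata for tested accession {acc!r}")
        if row.get("call", "none") == "none":
            report.excluded["not_significant"].append(acc)
            continue
        info = meta.loc[acc]
        description = str(info.get("description", ""))
        gene = str(info.get("gene_symbol", ""))
        reported = str(info.get("reported_accession", acc))
        compartment = str(row.get("compartment", ""))
        for rule in rules:
            if rule.matches(description, gene, reported, compartment):
                report.excluded[rule.name].append(acc)
                break
        else:
            keep_rows.append(row)

    retained = pd.DataFrame(keep_rows, columns=results.columns).reset_index(drop=True)
    report.retained_count = len(retained)
    assert report.retained_count + report.total_excluded() == report.input_count
    return retained, report


def curation_report(report: CurationReport) -> tuple[str, pd.DataFrame]:
    """Render a curation ledger as summary text plus a tidy per-rule table."""
    rows = [
        {"rule": rule, "excluded": len(accs), "accessions": ";".join(map(str, accs))}
        for rule, accs in report.excluded.items()
    ]
    frame = pd.DataFrame(rows, columns=["rule", "excluded", "accessions"])
    lines = [f"curation: {report.input_count} in, {report.retained_count} retained"]
    for _, row in frame.iterrows():
        lines.append(f"  excluded by {row['rule']}: {row['excluded']}")
    return "\n".join(lines), frame
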