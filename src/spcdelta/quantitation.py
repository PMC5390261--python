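"""Spectral-count quantitation: normalized spectral counts and the Rsc statistic.

The spectral count (SpC) of a protein is the number of significant MS/MS
spectra assigned to its peptides in a sample, a proxy for abundance.  Two
derived representations are used downstream:

* **NSpC** — the SpC divided by the sample's total significant spectra,
  normalizing for per-sample acquisition depth.  Used for correlation /
  clustering and reporting.
* **Rsc** — a log2 relative-abundance ratio between two conditions computed
  from counts pooled over all replicates of each condition, with a
  pseudocount ``f`` stabilizing low counts.  Used together with Fisher's
  exact test for differential calls.

With ``n1, n2`` the pooled counts of a protein in the two conditions and
``t1, t2`` the pooled totals over all proteins::

    Rsc = log2((n2 + f) / (n1 + f)) + log2((t1 - n1 + f) / (t2 - n2 + f))

oriented so that a positive Rsc means higher abundance in condition 2
(here: the knockdown relative to the vector control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLE_ID_FIELDS",
    "CountMatrix",
    "PooledCounts",
    "parse_sample_id",
    "make_sample_id",
    "normalize_counts",
    "pool_replicates",
    "compute_rsc",
]

SAMPLE_ID_FIELDS = ("condition", "compartment", "biological", "technical")


def make_sample_id(condition: str, compartment: str, biological: int, technical: int) -> str:
    """Encode sample metadata in the canonical ``condition.compartment.bioN.techM`` id."""
    for label in (condition, compartment):
        if "." in label or not label:
            raise ValueError(f"condition/compartment labels must be non-empty and dot-free: {label!r}")
    return f"{condition}.{compartment}.bio{int(biological)}.tech{int(technical)}"


def parse_sample_id(sample_id: str) -> dict:
    """Decode ``condition.compartment.bioN.techM`` into its metadata fields.

    Raises ValueError on any malformed id.
    """
    parts = sample_id.split(".")
    if len(parts) != 4:
        raise ValueError(f"malformed sample id {sample_id!r}: expected 'condition.compartment.bioN.techM'")
    condition, compartment, bio, tech = parts
    if not bio.startswith("bio") or not tech.startswith("tech"):
        raise ValueError(f"malformed sample id {sample_id!r}: replicate tokens must be 'bioN'/'techM'")
    try:
        biological = int(bio[3:])
        technical = int(tech[4:])
    except ValueError as exc:
        raise ValueError(f"malformed sample id {sample_id!r}: non-integer replicate index") from exc
    if not condition or not compartment:
        raise ValueError(f"malformed sample id {sample_id!r}: empty condition or compartment")
    return {
        "condition": condition,
        "compartment": compartment,
        "biological": biological,
        "technical": technical,
    }


@dataclass
class CountMatrix:
    """Spectral counts per protein per sample, with decoded sample metadata.

    Parameters
    ----------
    counts
        Integer DataFrame, index = protein accessions (unique), columns =
        sample ids in the ``condition.compartment.bioN.techM`` dialect.
    samples
        Optional metadata frame (index = sample id, columns = condition,
        compartment, biological, technical).  Decoded from the sample ids
        when omitted.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate accessions in count matrix: {dups}")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in count matrix: {dups}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("count matrix contains non-integer cells")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            i, j = np.argwhere(counts.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at protein {counts.index[i]!r}, sample {counts.columns[j]!r}"
            )
        self.counts = counts
        if self.samples is None:
            self.samples = pd.DataFrame(
                [parse_sample_id(s) for s in counts.columns], index=counts.columns
            )
        else:
            missing = [s for s in counts.columns if s not in self.samples.index]
            if missing:
                raise ValueError(f"samples metadata missing ids: {missing}")
            self.samples = self.samples.loc[counts.columns]

    @property
    def accessions(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_proteins(self, accessions) -> "CountMatrix":
        keep = [a for a in self.counts.index if a in set(accessions)]
        return CountMatrix(self.counts.loc[keep], self.samples)

    def select_samples(self, condition: str | None = None, compartment: str | None = None) -> list[str]:
        """Sample ids matching the given condition and/or compartment."""
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if compartment is not None:
            mask &= self.samples["compartment"] == compartment
        return list(self.samples.index[mask])


@dataclass
class PooledCounts:
    """Per-protein counts summed over all replicates of one (condition, compartment).

    ``n`` holds the pooled count per protein; ``t = n.sum()`` is the pooled
    total spectra for the condition (the Fisher/Rsc marginal).
    """

    n: pd.Series
    condition: str
    compartment: str

    @property
    def t(self) -> int:
        return int(self.n.sum())


def normalize_counts(matrix: CountMatrix) -> pd.DataFrame:
    """Normalized spectral counts: each sample's column divided by its total.

    Every column of the result sums to 1.  A sample with zero total spectra
    is uninterpretable and raises, naming the sample.
    """
    totals = matrix.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"cannot normalize: zero total spectral count in sample(s) {zero}")
    return matrix.counts / totals


def pool_replicates(matrix: CountMatrix, condition: str, compartment: str) -> PooledCounts:
    """Sum each protein's counts over all biological and technical replicates
    of one condition within one compartment."""
    cols = matrix.select_samples(condition=condition, compartment=compartment)
    if not cols:
        raise ValueError(f"no samples match condition={condition!r}, compartment={compartment!r}")
    pooled = matrix.counts[cols].sum(axis=1)
    return PooledCounts(n=pooled, condition=condition, compartment=compartment)


def compute_rsc(pooled_control: PooledCounts, pooled_kd: PooledCounts, f: float = 0.5):
    """Rsc per protein, oriented knockdown / control (positive = up in KD).

    ``f`` is the pseudocount (default 0.5) protecting proteins observed in
    only one condition from infinite ratios.
    """
    if f <= 0:
        raise ValueError("pseudocount f must be positive")
    n1 = pooled_control.n
    n2 = pooled_kd.n
    if not n1.index.equals(n2.index):
        raise ValueError("pooled structures must share the protein index")
    t1, t2 = pooled_control.t, pooled_kd.t
    if (n1 > t1).any() or (n2 > t2).any():
        raise ValueError("pooled count exceeds condition total")
    rsc = np.log2((n2 + f) / (n1 + f)) + np.log2((t1 - n1 + f) / (t2 - n2 + f))
    return pd.Series(rsc, index=n1.index, name="rsc")
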