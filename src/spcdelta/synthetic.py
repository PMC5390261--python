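"""Synthetic spectral-count data with known ground truth.

Emulates the structure of the study design the analysis assumes: two
conditions (vector control vs knockdown) crossed with up to three sample
compartments (cell lysate, secretome, tumor xenograft), with 4 biological
x 2 technical replicates per condition and compartment.  Counts are
overdispersed: each biological replicate draws a latent Poisson rate from a
gamma distribution (so the marginal per-sample count is negative-binomial
with the configured mean and dispersion), and technical replicates share
that latent rate, differing only by Poisson sampling noise.

A configurable fraction of proteins is truly differential, with log2 fold
changes symmetric in sign, and configurable fractions of nuisance entries
(keratins, accession-less rows, peptide fragments, putative uncharacterized
proteins, cDNA-like entries, skeletal-muscle contaminants) are injected to
exercise the curation filters.  Every allocation is a deterministic
stratified assignment from the seeded stream, so identical configurations
and seeds give bit-identical outputs.

The generator emulates count structure only; it does not simulate raw
spectra, retention times or search-engine scoring.  PSM probabilities (see
:func:`simulate_psms`) are drawn from simple configured distributions purely
to exercise the identification filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantitation import CountMatrix, make_sample_id

__all__ = [
    "NUISANCE_CLASSES",
    "SimulationConfig",
    "simulate_dataset",
    "inject_nuisance_entries",
    "simulate_psms",
    "truth_recovery_report",
]

#: Nuisance classes in their fixed allocation (and curation) order.
NUISANCE_CLASSES = (
    "keratin",
    "no_accession",
    "fragment",
    "uncharacterized",
    "cdna_like",
    "skeletal_muscle",
)

_NUISANCE_DESCRIPTIONS = {
    "keratin": "Keratin, type II cytoskeletal {i}",
    "no_accession": "Unassigned spectrum cluster {i}",
    "fragment": "Actin-binding protein {i} (Fragment)",
    "uncharacterized": "Putative uncharacterized protein C{i}orf{i}",
    "cdna_like": "cDNA FLJ{i}, highly similar to hypothetical protein",
    "skeletal_muscle": "Myosin-{i}, skeletal muscle isoform",
}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the synthetic generator.

    Defaults mirror the emulated design: three compartments, 4 biological x
    2 technical replicates per condition, overdispersed counts around a
    baseline mean of 20 spectra per protein per sample.
    """

    n_proteins: int = 2000
    compartments: tuple[str, ...] = ("cell", "secretome", "xenograft")
    conditions: tuple[str, str] = ("control", "kd")
    n_biological: int = 4
    n_technical: int = 2
    baseline_mean: float = 20.0
    #: Negative-binomial overdispersion: Var = mean + dispersion * mean^2.
    dispersion: float = 0.05
    #: Spread (log-normal sigma) of per-protein baseline abundances.
    abundance_sigma: float = 0.8
    de_fraction: float = 0.0
    fold_change_range: tuple[float, float] = (4.0, 16.0)
    nuisance_fractions: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.n_biological <= 0 or self.n_technical <= 0:
            raise ValueError("replicate counts must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        lo, hi = self.fold_change_range
        if lo <= 1 or hi < lo:
            raise ValueError("fold_change_range must be an increasing pair of reals > 1")
        if not self.compartments or not all(self.compartments):
            raise ValueError("at least one non-empty compartment label required")
        for cls, frac in self.nuisance_fractions.items():
            if cls not in NUISANCE_CLASSES:
                raise ValueError(f"unknown nuisance class {cls!r}; known: {NUISANCE_CLASSES}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"nuisance fraction for {cls!r} must lie in [0, 1]")
        total = self.de_fraction + sum(self.nuisance_fractions.values())
        if total > 1.0 + 1e-12:
            raise ValueError("de_fraction plus nuisance fractions exceed 1")

    @property
    def samples_per_condition(self) -> int:
        return self.n_biological * self.n_technical


def _sample_ids(config: SimulationConfig) -> list[str]:
    ids = []
    for condition in config.conditions:
        for compartment in config.compartments:
            for b in range(1, config.n_biological + 1):
                for t in range(1, config.n_technical + 1):
                    ids.append(make_sample_id(condition, compartment, b, t))
    return ids


def _allocate(config: SimulationConfig, rng: np.random.Generator):
    """Deterministic stratified allocation of DE and nuisance proteins.

    One permutation of the protein indices is drawn from the seeded stream;
    the first ``round(de_fraction * n)`` slots are differential, followed by
    one contiguous slice per nuisance class in fixed order, so all
    allocations are disjoint by construction.
    """
    n = config.n_proteins
    perm = rng.permutation(n)
    k_de = int(round(config.de_fraction * n))
    de_idx = np.sort(perm[:k_de])
    cursor = k_de
    nuisance_idx: dict[str, np.ndarray] = {}
    for cls in NUISANCE_CLASSES:
        frac = config.nuisance_fractions.get(cls, 0.0)
        k = int(round(frac * n))
        nuisance_idx[cls] = np.sort(perm[cursor : cursor + k])
        cursor += k
    return de_idx, nuisance_idx


def simulate_dataset(config: SimulationConfig):
    """Generate a (CountMatrix, protein table, ground-truth table) triple.

    The KD condition's expected count for a differential protein is the
    control mean scaled by ``2**true_log2_fc``; fold-change signs alternate
    (half up, half down) and magnitudes are uniform in log2 over
    ``fold_change_range``.  Nuisance entries (if configured) are injected via
    :func:`inject_nuisance_entries` and are never differential; counts for
    skeletal-muscle contaminants appear only in xenograft samples.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    accessions = np.array([f"SIM{i:05d}" for i in range(n)])

    de_idx, nuisance_idx = _allocate(config, rng)
    true_log2_fc = np.zeros(n)
    if de_idx.size:
        mags = rng.uniform(
            np.log2(config.fold_change_range[0]),
            np.log2(config.fold_change_range[1]),
            size=de_idx.size,
        )
        signs = np.where(np.arange(de_idx.size) % 2 == 0, 1.0, -1.0)
        true_log2_fc[de_idx] = signs * mags

    nuisance_class = np.array(["none"] * n, dtype=object)
    for cls, idx in nuisance_idx.items():
        nuisance_class[idx] = cls

    # Per-protein baseline abundance, log-normal with mean = baseline_mean.
    sigma = config.abundance_sigma
    mu = np.log(config.baseline_mean) - 0.5 * sigma**2
    base_mean = np.exp(rng.normal(mu, sigma, size=n)) if sigma > 0 else np.full(n, config.baseline_mean)

    sample_ids = _sample_ids(config)
    skeletal = nuisance_class == "skeletal_muscle"
    counts = np.zeros((n, len(sample_ids)), dtype=np.int64)
    col = 0
    for condition in config.conditions:
        fc = 2.0**true_log2_fc if condition == config.conditions[1] else np.ones(n)
        for compartment in config.compartments:
            mean = base_mean * fc
            if compartment != "xenograft":
                mean = np.where(skeletal, 0.0, mean)
            for _b in range(config.n_biological):
                if config.dispersion > 0:
                    shape = 1.0 / config.dispersion
                    lam = rng.gamma(shape, mean * config.dispersion)
                else:
                    lam = mean
                for _t in range(config.n_technical):
                    counts[:, col] = rng.poisson(lam)
                    col += 1

    matrix = CountMatrix(pd.DataFrame(counts, index=accessions, columns=sample_ids))
    proteins = pd.DataFrame(
        {
            "accession": accessions,
            "reported_accession": accessions,
            "gene_symbol": [f"GENE{i}" for i in range(n)],
            "description": [f"Simulated protein {i}" for i in range(n)],
            "decoy": False,
        }
    )
    truth = pd.DataFrame(
        {
            "accession": accessions,
            "true_log2_fc": true_log2_fc,
            "is_de": true_log2_fc != 0.0,
            "nuisance_class": "none",
        }
    )
    proteins, truth = inject_nuisance_entries(proteins, truth, config, _allocation=nuisance_idx)
    return matrix, proteins, truth


def inject_nuisance_entries(
    proteins: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    _allocation: dict | None = None,
):
    """Relabel a deterministic fraction of non-differential proteins as
    nuisance entries of each configured class.

    The rewritten records carry the descriptions/flags the curation rules
    key on (descriptions containing "Keratin", "(Fragment)", "Putative
    uncharacterized protein", "cDNA FLJ", "skeletal muscle"; or a blanked
    reported accession).  Skeletal-muscle entries are tagged as
    xenograft-only contaminants.  With all fractions zero the tables are
    returned unchanged.
    """
    proteins = proteins.reset_index(drop=True).copy()
    truth = truth.reset_index(drop=True).copy()
    if "nuisance_compartment" not in proteins.columns:
        proteins["nuisance_compartment"] = ""
    if _allocation is None:
        rng = np.random.default_rng(config.seed)
        _, _allocation = _allocate(config, rng)
    for cls, idx in _allocation.items():
        template = _NUISANCE_DESCRIPTIONS[cls]
        for j, i in enumerate(idx, start=1):
            proteins.loc[i, "description"] = template.format(i=j)
            if cls == "keratin":
                proteins.loc[i, "gene_symbol"] = f"KRT{j}"
            if cls == "no_accession":
                proteins.loc[i, "reported_accession"] = ""
            if cls == "skeletal_muscle":
                proteins.loc[i, "nuisance_compartment"] = "xenograft"
            truth.loc[i, "nuisance_class"] = cls
            truth.loc[i, "true_log2_fc"] = 0.0
            truth.loc[i, "is_de"] = False
    return proteins, truth


def simulate_psms(
    proteins: pd.DataFrame,
    seed: int = 0,
    peptides_per_protein: int = 4,
    shared_peptide_fraction: float = 0.1,
    decoy_fraction: float = 0.05,
    target_prob_beta: tuple[float, float] = (40.0, 1.0),
    decoy_prob_beta: tuple[float, float] = (2.0, 6.0),
) -> pd.DataFrame:
    """PSM table exercising the identification filters.

    Each target protein receives ``peptides_per_protein`` peptide matches
    with probabilities drawn Beta(40, 1) (concentrated near 1); a fraction
    of peptides is shared with a second protein to exercise parsimony
    grouping; decoy PSMs carry Beta(2, 6) probabilities.  This models only
    the *output* abstraction of a search engine, not its scoring.
    """
    rng = np.random.default_rng(seed)
    accs = proteins["accession"].tolist()
    rows = []
    spectrum = 0
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for k, acc in enumerate(accs):
        for p in range(peptides_per_protein):
            peptide = "".join(rng.choice(alphabet, size=9)) + f"K{k}P{p}"
            mapped = [acc]
            if rng.random() < shared_peptide_fraction and len(accs) > 1:
                other = accs[int(rng.integers(len(accs)))]
                if other != acc:
                    mapped.append(other)
            prob = float(rng.beta(*target_prob_beta))
            rows.append(
                {
                    "spectrum_id": f"sp{spectrum:07d}",
                    "peptide": peptide,
                    "mapped_accessions": ";".join(sorted(mapped)),
                    "probability": prob,
                    "decoy": False,
                    "significant": prob > 0.95,
                }
            )
            spectrum += 1
    n_decoys = int(round(decoy_fraction * len(rows)))
    for d in range(n_decoys):
        prob = float(rng.beta(*decoy_prob_beta))
        rows.append(
            {
                "spectrum_id": f"sp{spectrum:07d}",
                "peptide": "".join(rng.choice(alphabet, size=9)) + f"D{d}",
                "mapped_accessions": f"DECOY_{d:05d}",
                "probability": prob,
                "decoy": True,
                "significant": prob > 0.95,
            }
        )
        spectrum += 1
    return pd.DataFrame(rows)


def truth_recovery_report(truth: pd.DataFrame, results: pd.DataFrame) -> dict:
    """Confusion-matrix summary of differential calls against ground truth.

    Returns sensitivity (true differentials called), the observed false
    discovery rate among calls (0.0 by convention when nothing is called),
    and the sign agreement between the called direction and the true fold
    change over correctly called proteins.
    """
    merged = truth.merge(results, on="accession", how="inner")
    if merged.empty:
        raise ValueError("truth and results tables share no accessions")
    called = merged["call"] != "none"
    true_de = merged["is_de"].astype(bool)
    n_true = int(true_de.sum())
    n_called = int(called.sum())
    tp = int((called & true_de).sum())
    fp = int((called & ~true_de).sum())
    sensitivity = tp / n_true if n_true else float("nan")
    observed_fdr = fp / n_called if n_called else 0.0
    correct = merged[called & true_de]
    if len(correct):
        sign_agreement = float(
            (np.sign(correct["rsc"]) == np.sign(correct["true_log2_fc"])).mean()
        )
    else:
        sign_agreement = float("nan")
    return {
        "n_true_de": n_true,
        "n_called": n_called,
        "true_positives": tp,
        "false_positives": fp,
        "sensitivity": sensitivity,
        "observed_fdr": observed_fdr,
        "sign_agreement": sign_agreement,
    }
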