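"""Seeded generators for synthetic mutation cohorts and score tables.

The generator emulates the structure of per-cell mutation tables from
clonal-expansion studies of ageing epithelium: a cohort of single cells, a
per-cell mutation count distribution, positions placed uniformly (the
random-placement null) or by per-gene weights, a transition-dominated
substitution mix with a configurable strand-symmetric pair spectrum, a
heteroplasmy model mixing a homoplasmic point mass with continuous levels,
and a COX-status model tied to mutation burden.

Default parameters are calibrated to the headline marginals of ageing-colon
cohorts: 156 cells of which 89 carry mutations (count histogram
61/20/5/3 for 1/2/3/4+), ~90% transitions with ~65% of transitions being
C:G→T:A, and 39% of mutations homoplasmic.

All randomness flows through an explicit seed; no global RNG state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consequence import PAIR_LABELS
from .io import MutationSet
from .pathogenicity import PathogenicityTable
from .reference import CODING_END, CODING_START, GenomeAnnotation, N_PLACEHOLDER_POS

#: ref→alt rule for each strand-symmetric pair label.
_PAIR_RULE = {
    "C:G→T:A": {"C": "T", "G": "A"},
    "T:A→C:G": {"T": "C", "A": "G"},
    "C:G→A:T": {"C": "A", "G": "T"},
    "C:G→G:C": {"C": "G", "G": "C"},
    "T:A→A:T": {"T": "A", "A": "T"},
    "T:A→G:C": {"T": "G", "A": "C"},
}
TRANSITION_LABELS = ("C:G→T:A", "T:A→C:G")


def _normalized(d: dict, what: str) -> dict:
    total = sum(d.values())
    if total <= 0:
        raise ValueError(f"{what} probabilities must have positive sum")
    if any(v < 0 for v in d.values()):
        raise ValueError(f"{what} probabilities must be nonnegative")
    return {k: v / total for k, v in d.items()}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort (defaults: ageing-colon-like)."""

    cohort: str = "synthetic"
    n_cells: int = 156
    n_subjects: int = 9
    #: per-cell mutation count distribution {count: probability}
    mutations_per_cell: dict = field(
        default_factory=lambda: {0: 67 / 156, 1: 61 / 156, 2: 20 / 156, 3: 5 / 156, 4: 3 / 156}
    )
    positional_model: str = "uniform_coding"  # uniform_coding | uniform_genome | per_gene_weights
    gene_weights: dict = field(default_factory=dict)  # used by per_gene_weights
    #: substitution/indel mix
    type_mix: dict = field(
        default_factory=lambda: {
            "transition": 0.90,
            "transversion": 0.05,
            "deletion": 0.03,
            "insertion": 0.02,
        }
    )
    #: probabilities over the 6 strand-symmetric labels, renormalised within
    #: the transition / transversion families chosen by type_mix
    transition_pair_mix: dict = field(
        default_factory=lambda: {
            "C:G→T:A": 0.585,
            "T:A→C:G": 0.315,
            "C:G→A:T": 0.008,
            "C:G→G:C": 0.031,
            "T:A→A:T": 0.030,
            "T:A→G:C": 0.031,
        }
    )
    homoplasmic_probability: float = 0.39
    heteroplasmy_range: tuple[float, float] = (10.0, 95.0)
    #: P(COX deficient) for cells with a homoplasmic mutation / any mutation / none
    cox_model: dict = field(
        default_factory=lambda: {"homoplasmic": 0.88, "mutated": 0.45, "unmutated": 0.25}
    )
    inheritance_sporadic_probability: float | None = None  # None → not_applicable

    def __post_init__(self):
        for name in ("mutations_per_cell", "type_mix", "transition_pair_mix"):
            probs = _normalized(getattr(self, name), name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} does not normalise")
            object.__setattr__(self, name, probs)
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


def _candidate_positions(spec: CohortSpec, ann: GenomeAnnotation) -> np.ndarray:
    if spec.positional_model == "uniform_coding":
        pos = np.arange(CODING_START, CODING_END + 1)
    elif spec.positional_model == "uniform_genome":
        pos = np.arange(1, ann.genome.length + 1)
    elif spec.positional_model == "per_gene_weights":
        if not spec.gene_weights:
            raise ValueError("per_gene_weights needs a gene_weights mapping")
        pos = np.concatenate(
            [np.arange(ann.gene(sym).start, ann.gene(sym).end + 1) for sym in spec.gene_weights]
        )
    else:
        raise ValueError(f"unknown positional_model {spec.positional_model!r}")
    return pos[pos != N_PLACEHOLDER_POS]  # the rCRS N placeholder has no ref base


def generate_cohort(spec: CohortSpec, ann: GenomeAnnotation, seed: int) -> MutationSet:
    """Generate one cohort; identical (spec, annotation, seed) → identical output.

    Substitution ref bases are read from the reference so every record
    validates; the alternate base follows the requested pair label, with the
    position drawn uniformly among candidate positions whose reference base
    belongs to the label's ref pair (this honours the pair mix exactly while
    keeping placement uniform within each base family).
    """
    rng = np.random.default_rng(seed)
    genome = ann.genome
    candidates = _candidate_positions(spec, ann)
    bases = np.frombuffer(genome.sequence.encode(), dtype="S1")[candidates - 1]
    by_base = {b: candidates[bases == b.encode()] for b in "ACGT"}
    if spec.positional_model == "per_gene_weights":
        # per-position weight proportional to its gene's weight / gene length
        w = {}
        for sym, gw in _normalized(spec.gene_weights, "gene_weights").items():
            g = ann.gene(sym)
            for p in range(g.start, g.end + 1):
                w[p] = w.get(p, 0.0) + gw / g.length
        weight_of = np.vectorize(lambda p: w[p])
    else:
        weight_of = None

    counts = rng.choice(
        list(spec.mutations_per_cell), size=spec.n_cells, p=list(spec.mutations_per_cell.values())
    )
    kinds = list(spec.type_mix)
    kind_p = list(spec.type_mix.values())
    rows = []
    for cell_i in range(spec.n_cells):
        cell_id = f"cell{cell_i + 1:04d}"
        subject = f"subject{cell_i % spec.n_subjects + 1}"
        taken = set()
        for _ in range(int(counts[cell_i])):
            kind = rng.choice(kinds, p=kind_p)
            for _attempt in range(100):
                if kind in ("transition", "transversion"):
                    fam = TRANSITION_LABELS if kind == "transition" else tuple(
                        l for l in PAIR_LABELS if l not in TRANSITION_LABELS
                    )
                    p_fam = np.array([spec.transition_pair_mix[l] for l in fam])
                    label = rng.choice(fam, p=p_fam / p_fam.sum())
                    rule = _PAIR_RULE[label]
                    pool = np.concatenate([by_base[b] for b in rule])
                    if weight_of is not None:
                        pw = weight_of(pool)
                        position = int(rng.choice(pool, p=pw / pw.sum()))
                    else:
                        position = int(pool[rng.integers(len(pool))])
                    ref = genome.base(position)
                    alt = rule[ref]
                    rec_kind = "substitution"
                elif kind == "deletion":
                    if weight_of is not None:
                        pw = weight_of(candidates)
                        position = int(rng.choice(candidates, p=pw / pw.sum()))
                    else:
                        position = int(candidates[rng.integers(len(candidates))])
                    ref, alt, rec_kind = genome.base(position), "", "deletion"
                else:  # insertion
                    if weight_of is not None:
                        pw = weight_of(candidates)
                        position = int(rng.choice(candidates, p=pw / pw.sum()))
                    else:
                        position = int(candidates[rng.integers(len(candidates))])
                    ref, alt, rec_kind = "", rng.choice(list("ACGT")), "insertion"
                key = (position, alt)
                if key not in taken:
                    taken.add(key)
                    break
            het = (
                100.0
                if rng.random() < spec.homoplasmic_probability
                else float(np.round(rng.uniform(*spec.heteroplasmy_range), 1))
            )
            if spec.inheritance_sporadic_probability is None:
                inheritance = "not_applicable"
            else:
                inheritance = (
                    "sporadic"
                    if rng.random() < spec.inheritance_sporadic_probability
                    else "inherited"
                )
            rows.append(
                {
                    "cohort": spec.cohort,
                    "subject_id": subject,
                    "cell_id": cell_id,
                    "position": position,
                    "ref": ref,
                    "alt": alt,
                    "kind": rec_kind,
                    "heteroplasmy_percent": het,
                    "cox_status": "",  # filled below per cell
                    "inheritance": inheritance,
                    "reported_gene": "",
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "cohort", "subject_id", "cell_id", "position", "ref", "alt", "kind",
            "heteroplasmy_percent", "cox_status", "inheritance", "reported_gene",
        ],
    )
    # COX status per cell, conditional on burden
    cox_by_cell = {}
    burden = df.groupby("cell_id")["heteroplasmy_percent"].max() if len(df) else {}
    for cell_i in range(spec.n_cells):
        cell_id = f"cell{cell_i + 1:04d}"
        if len(df) and cell_id in burden and burden[cell_id] == 100.0:
            p_def = spec.cox_model["homoplasmic"]
        elif len(df) and cell_id in burden.index:
            p_def = spec.cox_model["mutated"]
        else:
            p_def = spec.cox_model["unmutated"]
        cox_by_cell[cell_id] = "deficient" if rng.random() < p_def else "positive"
    if len(df):
        df["cox_status"] = df["cell_id"].map(cox_by_cell)
    ms = MutationSet(df, cohort=spec.cohort, provenance=f"synthetic cohort, seed {seed}")
    ms.validate_reference(genome)
    return ms


def generate_score_table(
    enumeration: pd.DataFrame,
    seed: int,
    beta_a: float = 5.58,
    beta_b: float = 3.11,
) -> PathogenicityTable:
    """Synthetic pathogenicity-score table over every distinct amino-acid
    variation in an enumeration, scores ~ Beta(a, b) on [0,1].

    The default Beta(5.58, 3.11) matches a mean near 0.64 and sd near 0.15,
    the marginal shape of published all-possible-variant score tables.
    """
    rng = np.random.default_rng(seed)
    missense = enumeration[enumeration["change_class"] == "non_synonymous"]
    keys = missense.drop_duplicates(["gene", "aa_pos", "aa_ref", "aa_alt"])[
        ["gene", "aa_pos", "aa_ref", "aa_alt"]
    ].reset_index(drop=True)
    keys = keys.assign(score=rng.beta(beta_a, beta_b, size=len(keys)))
    return PathogenicityTable(keys)


def selection_detection_power(
    enum: pd.DataFrame,
    retention: float = 0.5,
    n_unselected: int = 81,
    n_selected: int = 155,
    n_replicates: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Power of the 2×3 spectrum contingency test to detect purifying
    selection of a given strength.

    The null class distribution (synonymous / non-synonymous / stop-gain) is
    taken from the exhaustive enumeration, i.e. uniform random substitution
    in protein CDS. The selected cohort keeps amino-acid-changing classes
    with the given retention probability; conditioning on the retained
    sample size makes its class distribution the retention-tilted null.
    Returns the fraction of replicates where the Pearson chi-squared
    comparison of an unselected sample (n_unselected) against a selected
    sample (n_selected) rejects at level alpha.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    frac = enum["change_class"].value_counts(normalize=True)
    p_null = np.array(
        [frac.get("synonymous", 0), frac.get("non_synonymous", 0),
         frac.get("premature_termination", 0)]
    )
    tilt = p_null * np.array([1.0, retention, retention])
    tilt = tilt / tilt.sum()
    a = rng.multinomial(n_unselected, p_null, size=n_replicates).astype(float)
    b = rng.multinomial(n_selected, tilt, size=n_replicates).astype(float)
    row = a + b  # per-class totals, replicate × 3
    n = n_unselected + n_selected
    with np.errstate(divide="ignore", invalid="ignore"):
        ea = row * n_unselected / n
        eb = row * n_selected / n
        contrib = np.where(row > 0, (a - ea) ** 2 / ea + (b - eb) ** 2 / eb, 0.0)
    stat = np.nansum(contrib, axis=1)
    df = (row > 0).sum(axis=1) - 1
    p = sps.chi2.sf(stat, df=np.maximum(df, 1))
    return float((p < alpha).mean())


def spike_selection(
    annotated: pd.DataFrame,
    depletion: float,
    seed: int,
    classes: tuple[str, ...] = ("non_synonymous", "premature_termination", "frameshift"),
) -> pd.DataFrame:
    """Thin amino-acid-changing mutations to mimic purifying selection.

    Each mutation whose change_class is in `classes` is independently
    retained with probability `depletion` (1.0 → identity, 0.0 → all such
    mutations removed). Input is an annotated mutation DataFrame; rows of
    other classes are always kept. Used for power analyses of the
    cohort-comparison tests.
    """
    if not 0.0 <= depletion <= 1.0:
        raise ValueError("depletion must be in [0, 1]")
    rng = np.random.default_rng(seed)
    target = annotated["change_class"].isin(classes).to_numpy()
    keep = ~target | (rng.random(len(annotated)) < depletion)
    return annotated[keep].reset_index(drop=True)
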