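"""Pathogenicity-score lookup and score-distribution summaries.

Scores are consumed from a precomputed table keyed by amino-acid change
(gene, aa_pos, aa_ref, aa_alt), one probability in [0,1] per variant, higher
meaning more likely pathogenic. The package never computes such scores.

Conventions follow the comparative analysis the package implements:
non-synonymous substitutions are scored by lookup; synonymous changes can be
assigned a score of 0 (they do not change a residue) when the
``synonymous_as_zero`` flag is on, and are otherwise excluded; frameshift and
premature-termination changes are always excluded because residue-substitution
predictors cannot score them; lookup misses are flagged and excluded from
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KEY = ["gene", "aa_pos", "aa_ref", "aa_alt"]


class ScoreTableError(ValueError):
    pass


class PathogenicityTable:
    """Mapping (gene, aa_pos, aa_ref, aa_alt) → score in [0,1]."""

    def __init__(self, df: pd.DataFrame):
        missing = set(KEY + ["score"]) - set(df.columns)
        if missing:
            raise ScoreTableError(f"score table missing columns: {sorted(missing)}")
        df = df.copy()
        df["aa_pos"] = df["aa_pos"].astype(int)
        df["score"] = pd.to_numeric(df["score"], errors="raise")
        if ((df["score"] < 0) | (df["score"] > 1)).any():
            bad = df.index[(df["score"] < 0) | (df["score"] > 1)].tolist()[:10]
            raise ScoreTableError(f"scores outside [0,1] at rows {bad}")
        if df.duplicated(KEY).any():
            bad = df.index[df.duplicated(KEY)].tolist()[:10]
            raise ScoreTableError(f"duplicate variant keys at rows {bad}")
        self.df = df.reset_index(drop=True)
        self._map = dict(zip(zip(df["gene"], df["aa_pos"], df["aa_ref"], df["aa_alt"]),
                             df["score"].astype(float)))

    def __len__(self) -> int:
        return len(self.df)

    def get(self, gene: str, aa_pos: int, aa_ref: str, aa_alt: str) -> float | None:
        return self._map.get((gene, int(aa_pos), aa_ref, aa_alt))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def load_score_table(path) -> PathogenicityTable:
    """Read a delimited score table with columns gene, aa_pos, aa_ref,
    aa_alt, score; duplicate keys and out-of-range scores are rejected."""
    df = pd.read_csv(path, sep=None, engine="python")
    return PathogenicityTable(df)


@dataclass(frozen=True)
class SummaryStats:
    """mean ± sd (sample, n−1 denominator) over n scored entries."""

    mean: float
    sd: float
    n: int

    def __str__(self) -> str:
        return f"{self.mean:.3f}±{self.sd:.3f} (sd), n = {self.n}"


@dataclass
class ScoredSet:
    """Per-mutation scores for one cohort under an explicit convention."""

    df: pd.DataFrame  # annotated rows + score, scored, reason columns
    synonymous_as_zero: bool
    cohort: str = ""

    @property
    def scores(self) -> np.ndarray:
        return self.df.loc[self.df["scored"], "score"].to_numpy(dtype=float)


def score_mutations(
    annotated: pd.DataFrame,
    table: PathogenicityTable,
    synonymous_as_zero: bool = False,
    collapse_duplicates: bool = False,
    cohort: str = "",
) -> ScoredSet:
    """Attach scores to an annotated mutation table.

    collapse_duplicates keeps one row per distinct amino-acid change before
    scoring (recurrent variants counted once), matching analyses that treat
    the variant, not the observation, as the unit.
    """
    df = annotated.copy()
    if collapse_duplicates:
        protein_sub = (df["gene_type"] == "protein") & df["aa_change"].notna()
        dup = protein_sub & df.duplicated(["gene", "aa_change"])
        df = df[~dup]
    scores, scored, reasons = [], [], []
    for r in df.itertuples():
        if r.gene_type != "protein":
            scores.append(np.nan); scored.append(False); reasons.append("not protein-coding")
        elif r.change_class in ("frameshift", "premature_termination", "stop_loss",
                                "in_frame_indel"):
            scores.append(np.nan); scored.append(False); reasons.append("not scoreable")
        elif r.change_class == "synonymous":
            if synonymous_as_zero:
                scores.append(0.0); scored.append(True); reasons.append("synonymous → 0")
            else:
                scores.append(np.nan); scored.append(False); reasons.append("synonymous excluded")
        else:  # non_synonymous
            s = table.get(r.gene, r.aa_pos, r.aa_ref, r.aa_alt)
            if s is None:
                scores.append(np.nan); scored.append(False); reasons.append("lookup miss")
            else:
                scores.append(s); scored.append(True); reasons.append("lookup")
    df = df.assign(score=scores, scored=scored, score_reason=reasons)
    return ScoredSet(df=df.reset_index(drop=True),
                     synonymous_as_zero=synonymous_as_zero, cohort=cohort)


def summarize_scores(s: ScoredSet | np.ndarray) -> SummaryStats:
    """Mean, sample sd and n over scored entries (sd = 0 when n = 1)."""
    values = s.scores if isinstance(s, ScoredSet) else np.asarray(s, dtype=float)
    if len(values) == 0:
        raise ScoreTableError("no scored entries to summarize")
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return SummaryStats(mean=float(np.mean(values)), sd=sd, n=int(len(values)))
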