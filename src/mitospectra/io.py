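"""Reading, validating, and summarising cohort mutation tables.

The table schema mirrors per-cell mutation lists from single-cell
mitochondrial sequencing studies: one row per clonally expanded point
mutation, with position/ref/alt in rCRS coordinates plus cell, heteroplasmy,
COX-status and inheritance metadata. Files are UTF-8, comma- or tab-delimited
(sniffed); "." or empty fields mean unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import CODING_END, CODING_START, ReferenceGenome

REQUIRED_COLUMNS = ("position", "ref", "alt")
CANONICAL_COLUMNS = (
    "cohort",
    "subject_id",
    "cell_id",
    "position",
    "ref",
    "alt",
    "kind",
    "heteroplasmy_percent",
    "cox_status",
    "inheritance",
    "reported_gene",
)
KINDS = ("substitution", "insertion", "deletion")
COX_STATUSES = ("positive", "deficient", "unknown")
INHERITANCES = ("inherited", "sporadic", "not_applicable")


class ValidationError(ValueError):
    """Raised when a mutation table violates the schema, listing offending rows."""


@dataclass(frozen=True)
class PointMutation:
    """One mitochondrial point mutation in rCRS (H-strand) orientation."""

    position: int
    ref: str
    alt: str
    kind: str = "substitution"
    heteroplasmy: float | None = None  # percent, None if unknown
    subject_id: str = ""
    cell_id: str = ""
    cox_status: str = "unknown"
    inheritance: str = "not_applicable"
    cohort: str = ""

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(f"unknown kind {self.kind!r}")
        if self.kind == "substitution":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValidationError("substitution needs single-base ref and alt")
            if self.ref == self.alt:
                raise ValidationError("substitution ref equals alt")
        elif self.kind == "deletion":
            if not self.ref or self.alt:
                raise ValidationError("deletion needs nonempty ref and empty alt")
        elif self.kind == "insertion":
            if self.ref or not self.alt:
                raise ValidationError("insertion needs empty ref and nonempty alt")

    @property
    def label(self) -> str:
        """m.-style label, e.g. m.3243A>G."""
        if self.kind == "substitution":
            return f"m.{self.position}{self.ref}>{self.alt}"
        if self.kind == "deletion":
            return f"m.{self.position}del{self.ref}"
        return f"m.{self.position}ins{self.alt}"


def _infer_kind(ref: str, alt: str) -> str:
    if ref and alt:
        return "substitution"
    return "deletion" if ref else "insertion"


class MutationSet:
    """An immutable-by-convention collection of mutations from one cohort.

    Backed by a pandas DataFrame in the canonical schema; extra input columns
    are preserved untouched. Iteration yields :class:`PointMutation` records.
    """

    def __init__(self, df: pd.DataFrame, cohort: str = "", provenance: str = ""):
        df = df.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col not in ("position", "heteroplasmy_percent") else np.nan
        df["position"] = pd.to_numeric(df["position"], errors="raise").astype(int)
        df["ref"] = df["ref"].fillna("").astype(str).str.upper().replace({".": "", "-": ""})
        df["alt"] = df["alt"].fillna("").astype(str).str.upper().replace({".": "", "-": ""})
        kind = df["kind"].fillna("").astype(str)
        inferred = [_infer_kind(r, a) for r, a in zip(df["ref"], df["alt"])]
        df["kind"] = np.where(kind.isin(KINDS), kind, inferred)
        df["heteroplasmy_percent"] = pd.to_numeric(
            df["heteroplasmy_percent"].replace({".": np.nan, "": np.nan}), errors="coerce"
        )
        df["cox_status"] = (
            df["cox_status"].fillna("unknown").replace({"": "unknown", ".": "unknown"})
        )
        df["inheritance"] = (
            df["inheritance"].fillna("not_applicable").replace({"": "not_applicable", ".": "not_applicable"})
        )
        if cohort:
            df["cohort"] = cohort
        elif df["cohort"].nunique() == 1 and len(df):
            cohort = str(df["cohort"].iloc[0])
        self.df = df.reset_index(drop=True)
        self.cohort = cohort
        self.provenance = provenance
        self._check_invariants()

    # -- container protocol ---------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for r in self.df.itertuples():
            het = None if pd.isna(r.heteroplasmy_percent) else float(r.heteroplasmy_percent)
            yield PointMutation(
                position=int(r.position),
                ref=r.ref,
                alt=r.alt,
                kind=r.kind,
                heteroplasmy=het,
                subject_id=str(r.subject_id),
                cell_id=str(r.cell_id),
                cox_status=str(r.cox_status),
                inheritance=str(r.inheritance),
                cohort=str(r.cohort),
            )

    def _check_invariants(self):
        bad = []
        for i, r in enumerate(self.df.itertuples()):
            if r.kind == "substitution" and (
                len(r.ref) != 1 or len(r.alt) != 1 or r.ref == r.alt
            ):
                bad.append((i, "malformed substitution"))
            elif r.kind == "deletion" and (not r.ref or r.alt):
                bad.append((i, "malformed deletion"))
            elif r.kind == "insertion" and (r.ref or not r.alt):
                bad.append((i, "malformed insertion"))
        if bad:
            raise ValidationError(f"invalid records (row, reason): {bad[:10]}")
        keyed = self.df[self.df["cell_id"].astype(str) != ""]
        dup = keyed.duplicated(subset=["cell_id", "position", "alt"])
        if dup.any():
            raise ValidationError(
                f"duplicate (cell_id, position, alt) rows: {list(keyed.index[dup])[:10]}"
            )

    def validate_reference(self, genome: ReferenceGenome) -> None:
        """Check ref bases of substitutions/deletions against the reference."""
        bad = []
        for i, r in enumerate(self.df.itertuples()):
            if not 1 <= r.position <= genome.length:
                bad.append((i, f"position {r.position} outside genome"))
                continue
            if r.kind in ("substitution", "deletion"):
                expect = genome.slice(r.position, r.position + len(r.ref) - 1)
                if r.ref != expect:
                    bad.append((i, f"ref {r.ref!r} != reference {expect!r} at {r.position}"))
        if bad:
            raise ValidationError(f"reference mismatches (row, reason): {bad[:20]}")

    # -- construction / serialisation -----------------------------------

    @classmethod
    def from_mutations(cls, mutations, cohort: str = "", provenance: str = "") -> "MutationSet":
        rows = [
            {
                "cohort": m.cohort or cohort,
                "subject_id": m.subject_id,
                "cell_id": m.cell_id,
                "position": m.position,
                "ref": m.ref,
                "alt": m.alt,
                "kind": m.kind,
                "heteroplasmy_percent": np.nan if m.heteroplasmy is None else m.heteroplasmy,
                "cox_status": m.cox_status,
                "inheritance": m.inheritance,
                "reported_gene": "",
            }
            for m in mutations
        ]
        df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        return cls(df, cohort=cohort, provenance=provenance)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out["heteroplasmy_percent"] = out["heteroplasmy_percent"].map(
            lambda v: "." if pd.isna(v) else f"{v:g}"
        )
        out.to_csv(path, sep="\t", index=False)

    def to_vcf(self, path, genome: ReferenceGenome) -> None:
        """Minimal VCF export (CHROM=chrMT; anchor-base convention for indels)."""
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID=chrMT,length={genome.length}>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        for m in self:
            if m.kind == "substitution":
                pos, ref, alt = m.position, m.ref, m.alt
            elif m.kind == "deletion":
                anchor = genome.base(m.position - 1)
                pos, ref, alt = m.position - 1, anchor + m.ref, anchor
            else:  # insertion after the anchor base at m.position
                anchor = genome.base(m.position)
                pos, ref, alt = m.position, anchor, anchor + m.alt
            lines.append(f"chrMT\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.")
        Path(path).write_text("\n".join(lines) + "\n")

    def subset(self, mask, provenance: str = "") -> "MutationSet":
        return MutationSet(
            self.df[mask].reset_index(drop=True),
            cohort=self.cohort,
            provenance=provenance or self.provenance,
        )


def read_mutation_table(
    path,
    cohort: str = "",
    genome: ReferenceGenome | None = None,
) -> MutationSet:
    """Parse a delimited cohort mutation table (delimiter sniffed).

    When a reference genome is supplied, ref bases are validated against it
    and mismatches reported with row numbers.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"missing required columns: {sorted(missing)}")
    try:
        df["position"] = pd.to_numeric(df["position"], errors="raise").astype(int)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable position column: {exc}") from exc
    ms = MutationSet(df, cohort=cohort, provenance=f"read from {path}")
    if genome is not None:
        ms.validate_reference(genome)
    return ms


def filter_coding_region(
    ms: MutationSet, start: int = CODING_START, end: int = CODING_END
) -> MutationSet:
    """Keep mutations inside the coding region (everything but the control
    region), 577-16023 inclusive by default; order preserved."""
    mask = (ms.df["position"] >= start) & (ms.df["position"] <= end)
    return ms.subset(mask, provenance=f"coding-region filter {start}-{end}")


def cell_mutation_profile(ms: MutationSet) -> pd.DataFrame:
    """Per-cell mutation counts and homoplasmy flags.

    Homoplasmic means the reported heteroplasmy is exactly 100%. Returns a
    DataFrame indexed by cell_id with columns n_mutations and n_homoplasmic.
    """
    df = ms.df
    homo = (df["heteroplasmy_percent"] == 100).astype(int)
    out = (
        pd.DataFrame({"cell_id": df["cell_id"], "homo": homo})
        .groupby("cell_id")
        .agg(n_mutations=("homo", "size"), n_homoplasmic=("homo", "sum"))
    )
    return out


def count_histogram(profile: pd.DataFrame, cap: int = 4) -> dict[str, int]:
    """Histogram of per-cell mutation counts, topcoded as '>=cap'."""
    counts = profile["n_mutations"]
    hist = {str(k): int((counts == k).sum()) for k in range(1, cap)}
    hist[f">={cap}"] = int((counts >= cap).sum())
    return hist


def homoplasmic_fraction(ms: MutationSet) -> float:
    """Fraction of mutations reported at 100% heteroplasmy."""
    if not len(ms):
        raise ValidationError("empty mutation set")
    return float((ms.df["heteroplasmy_percent"] == 100).mean())
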