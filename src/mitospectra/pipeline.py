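"""End-to-end orchestration of the comparative spectrum analysis.

Given cohort mutation tables (or synthetic cohorts when none are supplied)
the pipeline produces, per cohort: gene-location, change-type and
consequence-class spectra; positional and gene-type randomness tests;
pairwise contingency comparisons with Bonferroni thresholds; pathogenicity
score summaries with Wilcoxon comparisons (all cohort pairs, with and
without the synonymous-as-zero convention, plus inherited-vs-sporadic within
the disease cohort); and a structured log of every filter with before/after
counts so the n-funnel is auditable.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import consequence as cq
from . import io as mio
from . import pathogenicity as pg
from . import stats as st
from . import synthetic as syn
from .reference import (
    CODING_END,
    CODING_START,
    GenomeAnnotation,
    annotation_from_table,
    load_gene_table,
    load_default_annotation,
    load_reference,
)


@dataclass
class AnalysisConfig:
    """File paths and flags driving one full analysis run."""

    reference_fasta: str | None = None  # None → bundled synthetic reference
    annotation_tsv: str | None = None  # None → bundled NC_012920.1 table
    cohort_tables: dict = field(default_factory=dict)  # label → path; empty → synthetic
    score_table: str | None = None  # None → synthetic Beta-distributed table
    coding_region: tuple[int, int] = (CODING_START, CODING_END)
    bin_size: int = 2000
    synonymous_as_zero: bool = True
    continuity_correction: bool = False
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "coding_region" in raw:
            raw["coding_region"] = tuple(raw["coding_region"])
        return cls(**raw)


def _load_annotation(cfg: AnalysisConfig) -> GenomeAnnotation:
    if cfg.reference_fasta is None and cfg.annotation_tsv is None:
        return load_default_annotation()
    table = load_gene_table(cfg.annotation_tsv)
    if cfg.reference_fasta is not None:
        genome = load_reference(cfg.reference_fasta)
    else:
        from .reference import synthetic_reference

        genome = synthetic_reference(table)
    return annotation_from_table(table, genome)


#: Cohort presets used when no tables are supplied: an ageing-colon-like
#: cohort (defaults), a population cohort whose amino-acid-changing mutations
#: are thinned to emulate germline purifying selection, and a disease cohort
#: weighted toward tRNA genes with inherited/sporadic labels.
def default_cohort_specs(ann: GenomeAnnotation) -> dict[str, dict]:
    trna_heavy = {g.symbol: (3.0 if g.gene_type == "tRNA" else 1.0) for g in ann.genes}
    return {
        "ageing": {"spec": syn.CohortSpec(cohort="ageing"), "depletion": None},
        "population": {
            "spec": syn.CohortSpec(
                cohort="population",
                n_cells=182,
                mutations_per_cell={1: 1.0},
                type_mix={"transition": 0.94, "transversion": 0.054,
                          "deletion": 0.004, "insertion": 0.002},
                homoplasmic_probability=1.0,
            ),
            "depletion": 0.2,  # germline purifying selection on aa-changing changes
        },
        "disease": {
            "spec": syn.CohortSpec(
                cohort="disease",
                n_cells=176,
                mutations_per_cell={1: 1.0},
                positional_model="per_gene_weights",
                gene_weights=trna_heavy,
                type_mix={"transition": 0.87, "transversion": 0.06,
                          "deletion": 0.04, "insertion": 0.03},
                homoplasmic_probability=0.25,
                inheritance_sporadic_probability=0.4,
            ),
            "depletion": None,
        },
    }


def _json_result(res: st.TestResult) -> dict:
    return {
        "method": res.method,
        "statistic": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "stars": res.stars,
        "thresholds": res.thresholds,
    }


def run_full_analysis(cfg: AnalysisConfig) -> dict:
    """Run every stage and return the report bundle as a nested dict.

    When cfg.output_dir is set, figure-ready spectrum tables (TSV) and the
    full report (JSON) are also written there.
    """
    ann = _load_annotation(cfg)
    log: list[dict] = []
    report: dict = {"log": log}

    # ---- load or simulate cohorts
    cohorts: dict[str, mio.MutationSet] = {}
    if cfg.cohort_tables:
        for label, path in cfg.cohort_tables.items():
            ms = mio.read_mutation_table(path, cohort=label, genome=ann.genome)
            cohorts[label] = ms
            log.append({"stage": f"load:{label}", "before": None, "after": len(ms)})
    else:
        for i, (label, preset) in enumerate(default_cohort_specs(ann).items()):
            ms = syn.generate_cohort(preset["spec"], ann, seed=cfg.seed + i)
            log.append({"stage": f"simulate:{label}", "before": None, "after": len(ms)})
            if preset["depletion"] is not None:
                annotated = cq.annotate_set(ms, ann)
                thinned = syn.spike_selection(
                    annotated, preset["depletion"], seed=cfg.seed + 100 + i
                )
                before = len(ms)
                ms = mio.MutationSet(thinned[list(mio.CANONICAL_COLUMNS)], cohort=label)
                log.append({"stage": f"selection-thinning:{label}",
                            "before": before, "after": len(ms)})
            cohorts[label] = ms

    # ---- coding-region filter
    coding: dict[str, mio.MutationSet] = {}
    for label, ms in cohorts.items():
        filtered = mio.filter_coding_region(ms, *cfg.coding_region)
        coding[label] = filtered
        log.append({"stage": f"coding-filter:{label}", "before": len(ms), "after": len(filtered)})

    annotated = {label: cq.annotate_set(ms, ann) for label, ms in coding.items()}

    # ---- spectra
    report["spectra"] = {}
    for label, ms in coding.items():
        adf = annotated[label]
        report["spectra"][label] = {
            "n": len(ms),
            "gene_location": cq.gene_location_spectrum(adf).round(1).to_dict(),
            "change_type": cq.change_type_spectrum(ms).round(1).to_dict(),
            "consequence": cq.consequence_spectrum(adf).round(1).to_dict(),
            "n_protein": int((adf["gene_type"] == "protein").sum()),
        }

    # ---- randomness tests (per cohort)
    report["randomness"] = {}
    for label, ms in coding.items():
        oe = st.positional_bins(ms, bin_size=cfg.bin_size, region=cfg.coding_region)
        report["randomness"][label] = {
            "positional": _json_result(st.chisq_goodness_of_fit(oe)),
            "gene_type": _json_result(st.gene_type_gof(ms, ann, region=cfg.coding_region)),
        }

    # ---- cross-cohort contingency comparisons
    def compare(counts_of) -> dict:
        groups = {label: counts_of(label) for label in coding}
        res = st.contingency_compare(groups, continuity=cfg.continuity_correction)
        return {
            "table": res.table.to_dict(),
            "overall": _json_result(res.overall),
            "pairwise": {f"{a} vs {b}": _json_result(r) for (a, b), r in res.pairwise.items()},
        }

    report["comparisons"] = {
        "gene_location": compare(
            lambda l: cq.gene_location_spectrum(annotated[l])["count"].to_dict()
        ),
        "change_type": compare(
            lambda l: cq.change_type_spectrum(coding[l])["count"].to_dict()
        ),
        "consequence": compare(
            lambda l: cq.consequence_spectrum(annotated[l])["count"]
            .loc[["synonymous", "non_synonymous", "frameshift_or_ptc"]]
            .to_dict()
        ),
    }

    # ---- pathogenicity scores
    enum = cq.enumerate_all_protein_variants(ann)
    if cfg.score_table is not None:
        table = pg.load_score_table(cfg.score_table)
        score_note = f"loaded from {cfg.score_table}"
    else:
        table = syn.generate_score_table(enum, seed=cfg.seed + 1000)
        score_note = "synthetic Beta-distributed table over the enumeration"
    all_possible = table.df["score"].to_numpy()

    scored = {
        label: pg.score_mutations(annotated[label], table, synonymous_as_zero=False,
                                  cohort=label)
        for label in coding
    }
    scored_with_syn = {
        label: pg.score_mutations(annotated[label], table, synonymous_as_zero=True,
                                  cohort=label)
        for label in coding
    }
    pools = {label: s.scores for label, s in scored.items()}
    pools["all_possible"] = all_possible
    pairs = list(itertools.combinations(pools, 2))
    thr = st.bonferroni_thresholds(len(pairs))
    wilcoxon = {}
    for a, b in pairs:
        if len(pools[a]) and len(pools[b]):
            r = st.wilcoxon_rank_sum(pools[a], pools[b])
            wilcoxon[f"{a} vs {b}"] = _json_result(
                st.TestResult(r.statistic, r.df, r.p_value, r.method,
                              correction=f"Bonferroni thresholds for {len(pairs)} tests",
                              thresholds=thr)
            )
    pools_syn = {label: s.scores for label, s in scored_with_syn.items()}
    pairs_syn = list(itertools.combinations(pools_syn, 2))
    thr_syn = st.bonferroni_thresholds(len(pairs_syn))
    wilcoxon_syn = {
        f"{a} vs {b}": _json_result(
            st.TestResult(*(lambda r: (r.statistic, r.df, r.p_value, r.method))(
                st.wilcoxon_rank_sum(pools_syn[a], pools_syn[b])),
                correction=f"Bonferroni thresholds for {len(pairs_syn)} tests",
                thresholds=thr_syn)
        )
        for a, b in pairs_syn
        if len(pools_syn[a]) and len(pools_syn[b])
    }
    report["scores"] = {
        "table": score_note,
        "summaries": {
            label: dataclasses.asdict(pg.summarize_scores(s))
            for label, s in scored.items()
            if len(s.scores)
        },
        "summaries_synonymous_as_zero": {
            label: dataclasses.asdict(pg.summarize_scores(s))
            for label, s in scored_with_syn.items()
            if len(s.scores)
        },
        "all_possible": dataclasses.asdict(pg.summarize_scores(all_possible)),
        "wilcoxon": wilcoxon,
        "wilcoxon_synonymous_as_zero": wilcoxon_syn,
    }

    # inherited vs sporadic within the disease cohort, if labels present
    if "disease" in annotated:
        adf = annotated["disease"]
        groups = {}
        for lab in ("inherited", "sporadic"):
            sub = adf[adf["inheritance"] == lab]
            if len(sub):
                groups[lab] = pg.score_mutations(sub, table, cohort=lab).scores
        if len(groups) == 2 and all(len(v) for v in groups.values()):
            report["scores"]["inherited_vs_sporadic"] = _json_result(
                st.wilcoxon_rank_sum(groups["inherited"], groups["sporadic"])
            )
            trunc = adf["change_class"].isin(["frameshift", "premature_termination"])
            tab = pd.crosstab(
                adf["inheritance"], trunc.map({True: "truncating", False: "other"})
            )
            if tab.shape == (2, 2):
                report["scores"]["inherited_vs_sporadic_truncating"] = _json_result(
                    st.chisq_contingency(tab, continuity=cfg.continuity_correction)
                )

    # ---- outputs
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, adf in annotated.items():
            adf.to_csv(out / f"annotated_{label}.tsv", sep="\t", index=False)
        for kind in ("gene_location", "change_type", "consequence"):
            pd.DataFrame(report["comparisons"][kind]["table"]).to_csv(
                out / f"table_{kind}.tsv", sep="\t"
            )
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
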