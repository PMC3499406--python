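"""Change-type classification, consequence annotation, and enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitospectra.consequence import (
    PAIR_LABELS,
    annotate,
    annotate_all,
    annotate_set,
    classify_change_type,
    consequence_spectrum,
    enumerate_all_protein_variants,
    enumeration_totals,
    strand_symmetric_label,
)
from mitospectra.io import MutationSet, PointMutation
from mitospectra.reference import MITO_CODON_TABLE, STOP_CODONS, translate

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def sub(position, ref, alt):
    return PointMutation(position=position, ref=ref, alt=alt)


@pytest.mark.parametrize(
    "ref,alt,expected",
    [("A", "G", "transition"), ("G", "A", "transition"), ("C", "T", "transition"),
     ("C", "A", "transversion"), ("T", "G", "transversion"), ("A", "T", "transversion")],
)
def test_classify_change_type(ref, alt, expected):
    assert classify_change_type(sub(100, ref, alt)) == expected


def test_classify_indels():
    assert classify_change_type(PointMutation(position=5, ref="A", alt="", kind="deletion")) == "deletion"
    assert classify_change_type(PointMutation(position=5, ref="", alt="AT", kind="insertion")) == "insertion"


@pytest.mark.parametrize(
    "ref,alt,label",
    [("G", "A", "C:G→T:A"), ("C", "T", "C:G→T:A"), ("C", "A", "C:G→A:T"),
     ("A", "G", "T:A→C:G"), ("T", "A", "T:A→A:T"), ("A", "C", "T:A→G:C")],
)
def test_strand_symmetric_label(ref, alt, label):
    assert strand_symmetric_label(sub(100, ref, alt)) == label


def test_strand_label_rejects_indels():
    with pytest.raises(ValueError):
        strand_symmetric_label(PointMutation(position=5, ref="A", alt="", kind="deletion"))


@settings(derandomize=True, max_examples=60)
@given(
    ref=st.sampled_from("ACGT"),
    alt=st.sampled_from("ACGT"),
)
def test_complement_invariance(ref, alt):
    """Complementing ref and alt together changes neither the change type
    nor the strand-collapsed pair label."""
    if ref == alt:
        return
    m = sub(100, ref, alt)
    mc = sub(100, _COMP[ref], _COMP[alt])
    assert classify_change_type(m) == classify_change_type(mc)
    assert strand_symmetric_label(m) == strand_symmetric_label(mc)
    assert strand_symmetric_label(m) in PAIR_LABELS


# -- annotation ----------------------------------------------------------


def brute_force_consequence(m, gene, ann):
    """Oracle: rebuild the whole genome with the mutation, re-extract and
    translate the entire protein, and diff residues."""
    seq = list(ann.genome.sequence)
    seq[m.position - 1] = m.alt
    raw = "".join(seq[gene.start - 1 : gene.end])
    cds = raw if gene.strand == "H" else raw.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    ref_prot = translate(ann.cds_sequence(gene.symbol))[: gene.n_aa_codons]
    alt_prot = translate(cds)[: gene.n_aa_codons]
    diffs = [(i + 1, a, b) for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if not diffs:
        return ("synonymous", None)
    assert len(diffs) == 1
    pos, aa_ref, aa_alt = diffs[0]
    klass = "premature_termination" if aa_alt == "*" else "non_synonymous"
    return (klass, (pos, aa_ref, aa_alt))


def random_protein_substitutions(ann, rng, n):
    prot_positions = []
    for g in ann.genes:
        if g.gene_type == "protein":
            prot_positions.append(ann.cds_positions(g.symbol)[: 3 * g.n_aa_codons])
    pool = np.unique(np.concatenate(prot_positions))
    for position in rng.choice(pool, size=n, replace=True):
        position = int(position)
        ref = ann.genome.base(position)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        yield sub(position, ref, str(alt))


def test_annotation_against_whole_protein_oracle(ann, rng):
    for m in random_protein_substitutions(ann, rng, 150):
        for c in annotate_all(m, ann):
            gene = ann.gene(c.gene)
            if m.position not in ann.cds_positions(gene.symbol)[: 3 * gene.n_aa_codons]:
                continue  # terminator of one gene inside another's reading frame
            klass, aa = brute_force_consequence(m, gene, ann)
            assert c.change_class == klass, m.label
            if aa is not None:
                assert (c.aa_pos, c.aa_ref, c.aa_alt) == aa, m.label


def test_synonymous_never_changes_protein(ann, rng):
    checked = 0
    for m in random_protein_substitutions(ann, rng, 300):
        c = annotate(m, ann)
        if c.change_class != "synonymous":
            continue
        klass, _ = brute_force_consequence(m, ann.gene(c.gene), ann)
        assert klass == "synonymous"
        checked += 1
    assert checked > 10


def test_indel_classes(ann):
    g = ann.gene("MT-ND1")
    pos = g.start + 30
    one = PointMutation(position=pos, ref=ann.genome.base(pos), alt="", kind="deletion")
    assert annotate(one, ann).change_class == "frameshift"
    three = PointMutation(position=pos, ref=ann.genome.slice(pos, pos + 2), alt="", kind="deletion")
    assert annotate(three, ann).change_class == "in_frame_indel"
    ins = PointMutation(position=pos, ref="", alt="AG", kind="insertion")
    assert annotate(ins, ann).change_class == "frameshift"


def test_rna_and_noncoding_classes(ann):
    t = annotate(sub(3243, ann.genome.base(3243), "G" if ann.genome.base(3243) != "G" else "A"), ann)
    assert (t.gene, t.change_class, t.gene_type) == ("MT-TL1", "tRNA", "tRNA")
    r = annotate(sub(1555, ann.genome.base(1555), "G" if ann.genome.base(1555) != "G" else "A"), ann)
    assert (r.gene, r.change_class) == ("MT-RNR1", "rRNA")
    nc = annotate(sub(100, ann.genome.base(100), "G" if ann.genome.base(100) != "G" else "A"), ann)
    assert nc.gene is None and nc.change_class == "noncoding"


def test_terminator_substitution_is_stop_loss_or_silent(ann):
    g = ann.gene("MT-CO1")  # complete TAA terminator
    term_pos = int(ann.cds_positions("MT-CO1")[-3])  # T of TAA
    m = sub(term_pos, ann.genome.base(term_pos), "C")
    c = annotate(m, ann)
    assert c.change_class in ("stop_loss", "synonymous")
    assert c.aa_ref == "*"
    # third base of TAA: A→G makes TAG, still a stop → synonymous
    last = int(ann.cds_positions("MT-CO1")[-1])
    c2 = annotate(sub(last, ann.genome.base(last), "G"), ann)
    assert c2.change_class == "synonymous"


def test_incomplete_stop_bases_are_stop_loss(ann):
    g = ann.gene("MT-ND3")  # single trailing T
    m = sub(g.end, ann.genome.base(g.end), "C")
    assert annotate(m, ann).change_class == "stop_loss"


def test_overlap_yields_one_call_per_gene(ann):
    ref = ann.genome.base(8529)
    m = sub(8529, ref, "A" if ref != "A" else "G")
    calls = annotate_all(m, ann)
    assert sorted(c.gene for c in calls) == ["MT-ATP6", "MT-ATP8"]
    primary = annotate(m, ann)
    severities = {"premature_termination": 0, "stop_loss": 1, "non_synonymous": 2, "synonymous": 4}
    assert severities[primary.change_class] == min(severities[c.change_class] for c in calls)


# -- enumeration ---------------------------------------------------------


def test_enumeration_identities(ann, enum):
    for g in ann.genes:
        if g.gene_type != "protein":
            continue
        sub_df = enum[enum["gene"] == g.symbol]
        assert len(sub_df) == 9 * g.n_aa_codons  # 3 substitutions per CDS base
        per_pos = sub_df.groupby("position").size()
        assert (per_pos == 3).all()
    totals = enumeration_totals(enum)
    assert totals["n_records"] == sum(totals["by_class"].values())
    assert totals["missense_distinct_aa"] <= totals["missense_events"]


def test_enumeration_matches_annotation(ann, enum, rng):
    """Every enumerated record agrees with the per-mutation annotator."""
    sample = enum.sample(n=200, random_state=7)
    for r in sample.itertuples():
        m = sub(int(r.position), r.ref, r.alt)
        calls = {c.gene: c for c in annotate_all(m, ann)}
        c = calls[r.gene]
        assert c.change_class == r.change_class
        assert (c.aa_pos, c.aa_ref, c.aa_alt) == (r.aa_pos, r.aa_ref, r.aa_alt)


def test_enumeration_ref_matches_reference(ann, enum):
    sample = enum.sample(n=300, random_state=8)
    for r in sample.itertuples():
        assert ann.genome.base(int(r.position)) == r.ref


def test_overlaps_enumerated_once_per_gene(enum):
    at_8529 = enum[enum["position"] == 8529]
    assert set(at_8529["gene"]) == {"MT-ATP6", "MT-ATP8"}
    assert len(at_8529) == 6  # 3 alts × 2 genes


# -- spectra -------------------------------------------------------------


def test_consequence_spectrum_pools_truncating(ann):
    g = ann.gene("MT-ND1")
    pos = g.start + 30
    muts = [PointMutation(position=pos, ref=ann.genome.base(pos), alt="", kind="deletion",
                          cell_id="c1")]
    # add a synonymous change found by scanning the enumeration
    enum = enumerate_all_protein_variants(ann)
    syn = enum[(enum["gene"] == "MT-ND1") & (enum["change_class"] == "synonymous")].iloc[0]
    muts.append(PointMutation(position=int(syn.position), ref=syn.ref, alt=syn.alt, cell_id="c2"))
    ms = MutationSet.from_mutations(muts, cohort="t")
    spec = consequence_spectrum(annotate_set(ms, ann))
    assert spec.loc["frameshift_or_ptc", "count"] == 1
    assert spec.loc["synonymous", "count"] == 1
    assert spec["percent"].sum() == pytest.approx(100.0)


def test_all_synonymous_spectrum(ann, enum):
    rows = enum[enum["change_class"] == "synonymous"].drop_duplicates("position").head(5)
    muts = [
        PointMutation(position=int(r.position), ref=r.ref, alt=r.alt, cell_id=f"c{i}")
        for i, r in enumerate(rows.itertuples())
    ]
    spec = consequence_spectrum(annotate_set(MutationSet.from_mutations(muts), ann))
    assert spec.loc["synonymous", "percent"] == pytest.approx(100.0)
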