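"""Genomic-context analyses against closed-form oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methdrift as md
from methdrift.context import CategoryCount


def probe(pid, entries, cgi="OpenSea", chrom="chr1", pos=100):
    return md.ProbeAnnotation(pid, chrom, pos, tuple(entries), cgi)


@pytest.mark.parametrize(
    "entries, expected",
    [
        ([("G", "TSS200")], "Promoter"),
        ([("G", "TSS1500")], "Promoter"),
        ([("G1", "Body"), ("G2", "TSS1500")], "Promoter"),  # promoter precedence
        ([("G1", "Body"), ("G2", "UTR5")], "UTR5"),
        ([("G1", "UTR3"), ("G2", "FirstExon")], "FirstExon"),
        ([("G", "Body")], "Body"),
        ([("G", "UTR3")], "UTR3"),
        ([], "Intergenic"),
    ],
)
def test_compartment_collapse_precedence(entries, expected):
    assert md.assign_compartment(probe("cg1", entries)) == expected


def test_compartment_assignment_is_total(recovery_sim):
    categories = {md.assign_compartment(a) for a in recovery_sim["annotation"].values()}
    assert categories <= set(("Promoter", "UTR5", "FirstExon", "Body", "UTR3", "Intergenic"))


def chi2_oracle(observed, expected):
    return sum((o - e) ** 2 / e for o, e in zip(observed, expected))


def test_background_test_identical_proportions():
    universe = ["A"] * 30 + ["B"] * 70
    selection = ["A"] * 3 + ["B"] * 7
    items = universe + selection  # categorizer = identity on labels
    counts, chi2, df, p = md.category_background_test(selection, universe, lambda x: x)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    assert df == 1


def test_background_test_oracle():
    universe = ["A"] * 50 + ["B"] * 30 + ["C"] * 20
    selection = ["A"] * 10 + ["B"] * 3 + ["C"] * 7
    counts, chi2, df, p = md.category_background_test(selection, universe, lambda x: x)
    expected = [0.5 * 20, 0.3 * 20, 0.2 * 20]
    assert chi2 == pytest.approx(chi2_oracle([10, 3, 7], expected), abs=1e-9)
    assert df == 2


@given(
    st.lists(st.integers(min_value=1, max_value=40), min_size=2, max_size=5),
    st.integers(min_value=0, max_value=2 ** 30),
)
@settings(max_examples=100, deadline=None)
def test_background_chi2_matches_closed_form(bg_counts, seed):
    rng = np.random.default_rng(seed)
    cats = [f"c{i}" for i in range(len(bg_counts))]
    universe = [c for c, k in zip(cats, bg_counts) for _ in range(k)]
    selection = list(rng.choice(universe, size=min(len(universe), 15)))
    counts, chi2, df, p = md.category_background_test(selection, universe, lambda x: x)
    expected = [bg / len(universe) * len(selection) for bg in bg_counts]
    observed = [selection.count(c) for c in cats]
    # order-align with the implementation's category order
    obs_by_cat = {c: selection.count(c) for c in cats}
    exp_by_cat = {c: e for c, e in zip(cats, expected)}
    oracle = sum((obs_by_cat[c] - exp_by_cat[c]) ** 2 / exp_by_cat[c] for c in cats)
    assert chi2 == pytest.approx(oracle, abs=1e-9)


def test_zero_background_category_merges_with_warning():
    universe = ["A"] * 5 + ["B"] * 5
    selection = ["A", "Z"]  # Z absent from background
    with pytest.warns(UserWarning, match="merged"):
        counts, chi2, df, p = md.category_background_test(selection, universe, lambda x: x)
    assert "other" in counts.observed


def _records(directions):
    rows = [
        {"probe_id": f"cg{i}", "direction": d, "is_grade_cpg": True, "rho": 1.0 if d == "hyper" else -1.0}
        for i, d in enumerate(directions)
    ]
    return pd.DataFrame(rows).set_index("probe_id")


def test_hyper_hypo_contrast_2x2_oracle():
    # counts [[24, 330], [351, 1280]]: 24/354 hypo and 351/1631 hyper in-feature
    directions = ["hypo"] * 354 + ["hyper"] * 1631
    records = _records(directions)
    in_feature = set(records.index[:24]) | set(records.index[354:354 + 351])
    ann = md.AnnotationTable(
        [probe(pid, [], cgi="Island" if pid in in_feature else "OpenSea") for pid in records.index]
    )
    pct_hypo, pct_hyper, chi2, p = md.hyper_hypo_contrast(records, ann, lambda a: a.cgi_relation == "Island")
    table = np.array([[24, 330], [351, 1280]], dtype=float)
    n = table.sum()
    exp = np.outer(table.sum(1), table.sum(0)) / n
    assert chi2 == pytest.approx(((table - exp) ** 2 / exp).sum(), abs=1e-9)
    assert pct_hypo == pytest.approx(100 * 24 / 354)
    assert pct_hyper == pytest.approx(100 * 351 / 1631)


def test_hyper_hypo_contrast_identical_rates():
    records = _records(["hypo"] * 10 + ["hyper"] * 10)
    flags = ([True] * 5 + [False] * 5) * 2
    ann = md.AnnotationTable([
        probe(pid, [], cgi="Island" if f else "OpenSea")
        for pid, f in zip(records.index, flags)
    ])
    _, _, chi2, p = md.hyper_hypo_contrast(records, ann, lambda a: a.cgi_relation == "Island")
    assert p == pytest.approx(1.0)


def test_hyper_hypo_contrast_singletons_run():
    records = _records(["hypo", "hyper"])
    ann = md.AnnotationTable([probe(pid, [], cgi="Island") for pid in records.index])
    _, _, chi2, p = md.hyper_hypo_contrast(records, ann, lambda a: a.cgi_relation == "Island")
    assert p == 1.0


def test_hyper_hypo_contrast_empty_group_errors():
    records = _records(["hyper", "hyper"])
    ann = md.AnnotationTable([probe(pid, []) for pid in records.index])
    with pytest.raises(md.ValidationError, match="hypo"):
        md.hyper_hypo_contrast(records, ann, lambda a: True)


@pytest.mark.parametrize(
    "beta, stratum",
    [
        (0.76, "High"), (0.75, "Intermediate"), (0.5, "Intermediate"),
        (0.25, "Intermediate"), (0.249, "Low"), (0.0, "Low"), (1.0, "High"),
    ],
)
def test_baseline_strata_boundaries(beta, stratum):
    assert md.baseline_strata(beta) == stratum


def test_strata_partition_is_exhaustive(recovery_sim):
    beta = recovery_sim["beta"]
    cohort = recovery_sim["cohort"]
    mean_n = beta.values[cohort.n_sample_ids()].mean(axis=1)
    strata = mean_n.map(md.baseline_strata)
    assert set(strata.unique()) <= {"High", "Intermediate", "Low"}
    assert strata.value_counts().sum() == len(beta.probe_ids)


def test_strata_rejects_out_of_range():
    with pytest.raises(md.ValidationError):
        md.baseline_strata(1.2)


def test_gene_overlap_self_overlap_oracle():
    genes = {"A", "B", "C", "D", "E"}
    overlap, k, p = md.gene_overlap(genes, genes, universe_size=20)
    assert k == 5
    assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)


def test_gene_overlap_disjoint():
    overlap, k, p = md.gene_overlap({"A"}, {"B"}, universe_size=10)
    assert k == 0 and p == pytest.approx(1.0)


def test_gene_overlap_case_insensitive_and_universe_check():
    overlap, k, _ = md.gene_overlap({"Lpl"}, {"LPL"}, universe_size=5)
    assert k == 1 and overlap == {"LPL"}
    with pytest.raises(md.ValidationError, match="universe"):
        md.gene_overlap({"A", "B"}, {"C"}, universe_size=2)


@given(st.data())
@settings(max_examples=60, deadline=None)
def test_hypergeometric_matches_enumeration(data):
    """Brute-force enumeration of all subsets on universes <= 15."""
    universe_size = data.draw(st.integers(min_value=2, max_value=15))
    genes = [f"g{i}" for i in range(universe_size)]
    n_a = data.draw(st.integers(min_value=1, max_value=universe_size))
    n_b = data.draw(st.integers(min_value=1, max_value=universe_size))
    a = set(genes[:n_a])
    b = set(data.draw(st.permutations(genes))[:n_b])
    overlap, k, p = md.gene_overlap(a, b, universe_size)
    # oracle: P(|A ∩ B'| >= k) over all equally likely placements B' of size |B|
    hits = 0
    total = 0
    for combo in itertools.combinations(genes, n_b):
        total += 1
        if len(a & set(combo)) >= k:
            hits += 1
    assert p == pytest.approx(hits / total, rel=1e-9, abs=1e-12)


SNPS = pd.DataFrame({"id": ["rs1", "rs2"], "chrom": ["chr1", "chr2"], "pos": [700_000, 700_000]})


@pytest.mark.parametrize(
    "chrom, pos, n_pairs",
    [
        ("chr1", 500_000, 1),   # 200 kb away, inside the window
        ("chr1", 450_000, 1),   # exactly 250 kb: inclusive boundary
        ("chr1", 449_999, 0),   # 250,001 bp: outside
        ("chr2", 700_000, 1),   # same position on the other chromosome
        ("chr3", 700_000, 0),   # chromosome mismatch
    ],
)
def test_snp_proximity_window(chrom, pos, n_pairs):
    probes = [probe("cgX", [], chrom=chrom, pos=pos)]
    pairs = md.snp_proximity(probes, SNPS, window_bp=250_000)
    assert len(pairs) == n_pairs
    if n_pairs:
        assert pairs["distance"].iloc[0] == abs(pos - 700_000)


def test_snp_proximity_rejects_malformed_rows():
    bad = pd.DataFrame({"id": ["rs1"], "chrom": ["chr1"], "pos": [np.nan]})
    with pytest.raises(md.ValidationError, match="malformed"):
        md.snp_proximity([probe("cgX", [])], bad, 1000)
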