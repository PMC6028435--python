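import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from degnet.clinical import (
    associate,
    association_grid,
    encode_tnm,
    spearman,
    ttest_groups,
)
from degnet.types import ClinicalTable


def midranks(v):
    """Average ranks for ties, built from scratch."""
    v = list(v)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den


class TestSpearman:
    def test_monotone_sequences(self):
        assert spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_tie_example_matches_hand_midranks(self):
        rho, _ = spearman([1, 2, 2, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(4.5 / np.sqrt(22.5), abs=1e-12)

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            x = rng.integers(0, 6, n).astype(float)   # heavy ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(pearson(midranks(x), midranks(y)), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = spearman(x, y)[0]
        assert spearman(np.exp(x), y)[0] == pytest.approx(base, abs=1e-12)
        assert spearman(x, y ** 3)[0] == pytest.approx(base, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry_and_sign_flip(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        assert spearman(x, y)[0] == pytest.approx(spearman(y, x)[0], abs=1e-12)
        assert spearman(x, -y)[0] == pytest.approx(-spearman(x, y)[0], abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])

    def test_exact_permutation_p_at_small_n(self):
        rho, p = spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], exact=True)
        assert rho == pytest.approx(1.0) and p == pytest.approx(2 / 120)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            spearman([1, 2], [1, 2])


class TestTtestGroups:
    def test_identical_groups_give_t_zero_p_one(self):
        t, p = ttest_groups([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(3)
        vals = np.r_[np.zeros(4), np.full(4, 10.0)] + rng.normal(0, 1e-3, 8)
        _, p = ttest_groups(vals, [0] * 4 + [1] * 4)
        assert p < 0.001

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            ttest_groups([1, 2, 3], [0, 1, 1])

    def test_type_one_error_near_alpha_under_null(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 2000
        for _ in range(n_sim):
            vals = rng.normal(size=30)
            _, p = ttest_groups(vals, [0] * 15 + [1] * 15)
            hits += p < 0.05
        assert abs(hits / n_sim - 0.05) < 0.02


class TestEncodeTnm:
    def test_string_labels_mapped(self):
        df = pd.DataFrame({"t": ["T1", "T4"], "n": ["N0", "N1"],
                           "m": ["M0", "M0"], "stage": ["I", "IV"]}, index=["a", "b"])
        enc = encode_tnm(df)
        assert list(enc.loc["b"]) == [4.0, 1.0, 0.0, 4.0]

    def test_numeric_columns_pass_through(self):
        df = pd.DataFrame({"t": [1, 2], "n": [0, 1]}, index=["a", "b"])
        enc = encode_tnm(df)
        assert list(enc["tumor_size"]) == [1.0, 2.0]

    def test_unmapped_label_rejected(self):
        df = pd.DataFrame({"t": ["T9"]}, index=["a"])
        with pytest.raises(ValueError, match="unmapped"):
            encode_tnm(df)


def clinical_fixture(n=60, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    expr = pd.DataFrame(
        {s: rng.lognormal(3, 1, 2) for s in samples}, index=["gA", "gB"])
    # gA strongly tracks tumor_size; gB is noise
    size = rng.integers(1, 5, n)
    expr.loc["gA"] = size * 10 + rng.normal(0, 1, n)
    clin = ClinicalTable(pd.DataFrame({
        "tumor_size": size,
        "node": rng.integers(0, 2, n),
        "metastasis": rng.integers(0, 2, n),
        "stage": rng.integers(1, 5, n),
    }, index=samples))
    return expr, clin


class TestAssociate:
    def test_planted_monotone_gene_found(self):
        expr, clin = clinical_fixture()
        results = associate(expr, clin)
        ga_size = next(r for r in results
                       if r.gene_id == "gA" and r.phenotype == "tumor_size")
        assert ga_size.rho > 0.9 and ga_size.p < 1e-6 and ga_size.stars == "**"

    def test_ttest_reported_for_metastasis(self):
        expr, clin = clinical_fixture()
        results = associate(expr, clin)
        assert any(r.phenotype == "metastasis_ttest" and r.method == "ttest"
                   for r in results)

    def test_constant_phenotype_skipped_with_warning(self, caplog):
        expr, clin = clinical_fixture()
        clin.data["stage"] = 2
        with caplog.at_level("WARNING"):
            results = associate(expr, clin)
        assert "constant" in caplog.text
        assert not any(r.phenotype == "stage" for r in results)

    def test_absent_gene_recorded_untested(self, caplog):
        expr, clin = clinical_fixture()
        with caplog.at_level("WARNING"):
            results = associate(expr, clin, genes=["gA", "missing"])
        assert any(r.gene_id == "missing" and r.method == "untested" for r in results)

    def test_too_few_aligned_samples_rejected(self):
        expr, clin = clinical_fixture()
        with pytest.raises(ValueError, match="aligned"):
            associate(expr[["s0", "s1"]], clin)

    def test_continuous_tumor_size_supported(self):
        expr, clin = clinical_fixture()
        clin.data["tumor_size_cm"] = clin.data["tumor_size"] * 0.5 + 0.2
        r_ord = next(r for r in associate(expr, clin)
                     if r.gene_id == "gA" and r.phenotype == "tumor_size")
        r_cm = next(r for r in associate(expr, clin, tumor_size_col="tumor_size_cm")
                    if r.gene_id == "gA" and r.phenotype == "tumor_size")
        # cm is a monotone recoding of the ordinal, so Spearman agrees
        assert r_cm.rho == pytest.approx(r_ord.rho, abs=1e-12)

    def test_grid_layout(self):
        expr, clin = clinical_fixture()
        grid = association_grid(associate(expr, clin))
        assert "tumor_size_r" in grid.columns and "tumor_size_P" in grid.columns
        assert set(grid.index) == {"gA", "gB"}
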