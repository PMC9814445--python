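import numpy as np
import pandas as pd
import pytest

from methylscreen.panel_design import (
    PROBE_SUFFIXES,
    SelectionThresholds,
    blood_filter,
    design_probe_set,
    differential_expression,
    differential_methylation,
    in_silico_convert,
    select_hcc_markers,
)
from tests.conftest import random_sequence


def bh_stepup_oracle(pvals):
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * n / rank)
        adjusted[idx] = running_min
    return adjusted


class TestDifferentialExpression:
    def _matrix(self, case, ctrl, n_genes=30, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.lognormal(3, 0.2, size=(n_genes, case + ctrl))
        return pd.DataFrame(
            data,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(case + ctrl)],
        ), np.array([True] * case + [False] * ctrl)

    def test_identical_groups_zero_log2fc(self):
        expr, _ = self._matrix(4, 4)
        mirrored = pd.concat([expr.iloc[:, :4], expr.iloc[:, :4]], axis=1)
        mirrored.columns = expr.columns
        out = differential_expression(mirrored, [True] * 4 + [False] * 4)
        assert np.allclose(out.log2fc, 0.0)

    def test_planted_fourfold_shift(self):
        expr, is_case = self._matrix(10, 10, seed=1)
        expr.iloc[0, :10] *= 4.0
        out = differential_expression(expr, is_case)
        assert out.log2fc.iloc[0] == pytest.approx(2.0, abs=0.3)
        assert out.fdr.iloc[0] < 0.05

    def test_zero_variance_flagged(self):
        expr, is_case = self._matrix(3, 3)
        expr.iloc[1] = 5.0
        out = differential_expression(expr, is_case)
        assert out.zero_variance.iloc[1]
        assert out.p_value.iloc[1] == 1.0

    def test_small_groups_error(self):
        expr, _ = self._matrix(1, 5, n_genes=3)
        with pytest.raises(ValueError):
            differential_expression(expr, [True] + [False] * 5)

    def test_bh_matches_stepup_oracle(self):
        rng = np.random.default_rng(7)
        pvals = rng.uniform(size=20)
        expr, is_case = self._matrix(5, 5, n_genes=20, seed=2)
        out = differential_expression(expr, is_case)
        # check statsmodels-backed FDR against the oracle on the same p-values
        from statsmodels.stats.multitest import multipletests

        assert np.allclose(multipletests(pvals, method="fdr_bh")[1], bh_stepup_oracle(pvals))
        assert np.allclose(out.fdr, bh_stepup_oracle(out.p_value))


class TestDifferentialMethylation:
    def test_identical_groups(self):
        beta = pd.DataFrame(np.full((5, 6), 0.4), columns=[f"s{i}" for i in range(6)])
        out = differential_methylation(beta, [True] * 3 + [False] * 3)
        assert np.allclose(out.delta_beta, 0.0)

    def test_planted_delta(self):
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(
            np.clip(rng.normal(0.3, 0.03, size=(10, 20)), 0, 1),
            index=[f"cg{i}" for i in range(10)],
        )
        beta.iloc[0, :10] += 0.4
        out = differential_methylation(beta, [True] * 10 + [False] * 10)
        assert out.delta_beta.iloc[0] == pytest.approx(0.4, abs=0.05)
        assert out.fdr.iloc[0] < 0.05

    def test_permuted_labels_near_uniform_p(self):
        rng = np.random.default_rng(5)
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, size=(300, 40)))
        labels = rng.permutation([True] * 20 + [False] * 20)
        out = differential_methylation(beta, labels)
        assert 0.35 < out.p_value.mean() < 0.65
        assert (out.p_value < 0.05).mean() < 0.15


def _toy_selection(n_cpgs=8):
    de = pd.DataFrame(
        {"log2fc": [-2.0] * n_cpgs, "fdr": [0.01] * n_cpgs},
        index=[f"g{i}" for i in range(n_cpgs)],
    )
    dm = pd.DataFrame(
        {"delta_beta": [0.4] * n_cpgs, "fdr": [0.01] * n_cpgs},
        index=[f"cg{i}" for i in range(n_cpgs)],
    )
    mapping = pd.DataFrame(
        {"cpg_id": [f"cg{i}" for i in range(n_cpgs)], "gene": [f"g{i}" for i in range(n_cpgs)]}
    )
    return de, dm, mapping


class TestSelectMarkers:
    def test_all_rules_pass(self):
        de, dm, mapping = _toy_selection(1)
        out = select_hcc_markers(de, dm, mapping)
        assert out.selected.all()

    def test_upregulated_gene_rejected(self):
        de, dm, mapping = _toy_selection(1)
        de.loc["g0", "log2fc"] = 2.0  # hypermethylated but upregulated
        out = select_hcc_markers(de, dm, mapping)
        assert not out.selected.any()

    def test_relaxed_thresholds_superset(self):
        rng = np.random.default_rng(11)
        n = 200
        de = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, n), "fdr": rng.uniform(size=n)},
            index=[f"g{i}" for i in range(n)],
        )
        dm = pd.DataFrame(
            {"delta_beta": rng.normal(0, 0.3, n), "fdr": rng.uniform(size=n)},
            index=[f"cg{i}" for i in range(n)],
        )
        mapping = pd.DataFrame(
            {"cpg_id": [f"cg{i}" for i in range(n)], "gene": [f"g{i}" for i in range(n)]}
        )
        strict = select_hcc_markers(de, dm, mapping, SelectionThresholds())
        relaxed = select_hcc_markers(
            de, dm, mapping,
            SelectionThresholds(fdr_expr=0.2, abs_log2fc=0.5, fdr_meth=0.2, abs_delta_beta=0.1),
        )
        strict_ids = set(strict.index[strict.selected])
        relaxed_ids = set(relaxed.index[relaxed.selected])
        assert strict_ids <= relaxed_ids


class TestBloodFilter:
    def _candidates(self, ids):
        return pd.DataFrame({"selected": True}, index=pd.Index(ids, name="cpg_id"))

    def test_blood_high_removed(self):
        cands = self._candidates(["cg0"])
        blood = pd.DataFrame({"b1": [0.9], "b2": [0.9]}, index=["cg0"])
        hcc = pd.DataFrame({"h1": [0.5], "h2": [0.5]}, index=["cg0"])
        kept, removed = blood_filter(cands, blood, hcc)
        assert removed == ["cg0"] and kept.empty

    def test_boundary_retained(self):
        cands = self._candidates(["cg0"])
        blood = pd.DataFrame({"b1": [0.55]}, index=["cg0"])
        hcc = pd.DataFrame({"h1": [0.5]}, index=["cg0"])
        kept, removed = blood_filter(cands, blood, hcc)  # 0.05 <= 0.1
        assert removed == [] and len(kept) == 1

    def test_missing_from_blood_retained(self):
        cands = self._candidates(["cgX"])
        blood = pd.DataFrame({"b1": [0.99]}, index=["cg0"])
        hcc = pd.DataFrame({"h1": [0.5]}, index=["cgX"])
        kept, removed = blood_filter(cands, blood, hcc)
        assert removed == [] and len(kept) == 1

    def test_random_matrices_match_bruteforce(self):
        rng = np.random.default_rng(4)
        ids = [f"cg{i}" for i in range(50)]
        blood = pd.DataFrame(rng.uniform(size=(50, 6)), index=ids)
        hcc = pd.DataFrame(rng.uniform(size=(50, 6)), index=ids)
        kept, removed = blood_filter(self._candidates(ids), blood, hcc, blood_delta=0.1)
        expected_removed = [
            cpg for cpg in ids if blood.loc[cpg].mean() - hcc.loc[cpg].mean() > 0.1
        ]
        assert removed == expected_removed
        assert list(kept.index) == [c for c in ids if c not in expected_removed]


class TestInSilicoConvert:
    @pytest.mark.parametrize(
        "seq,strand,assumption,expected",
        [
            ("ACGTCA", "watson", "unmethylated", "ATGTTA"),
            ("ACGTCA", "watson", "cpg_methylated", "ACGTTA"),
            ("ACGTCA", "crick", "cpg_methylated", "TGACGT"),
            ("ACGTCA", "crick", "unmethylated", "TGATGT"),
        ],
    )
    def test_hand_conversions(self, seq, strand, assumption, expected):
        assert in_silico_convert(seq, strand, assumption) == expected

    def test_n_preserved(self):
        assert in_silico_convert("ANCGT", "watson", "cpg_methylated") == "ANCGT"

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            in_silico_convert("ACGT", "middle")
        with pytest.raises(ValueError):
            in_silico_convert("ACGT", "watson", "hemimethylated")


@pytest.fixture(scope="module")
def ref():
    return random_sequence(1000, seed=77)


class TestDesignProbeSet:

    def _a_cpg(self, ref, min_pos=200):
        pos = ref.find("CG", min_pos)
        assert pos > 0
        return pos

    def test_five_probes_of_stated_length(self, ref):
        ps = design_probe_set(ref, self._a_cpg(ref))
        assert set(ps.probes) == set(PROBE_SUFFIXES)
        assert all(len(p) == 120 for p in ps.probes.values())

    def test_methylated_watson_differs_only_at_non_cpg_cs(self, ref):
        ps = design_probe_set(ref, self._a_cpg(ref))
        orig, meth = ps.probes["orig"], ps.probes["mW"]
        for i, (a, b) in enumerate(zip(orig, meth)):
            if a != b:
                assert a == "C" and b == "T"
                assert not (i + 1 < len(orig) and orig[i + 1] == "G")
            elif a == "C":
                assert i + 1 == len(orig) or orig[i + 1] == "G"

    def test_unmethylated_watson_differs_exactly_at_cs(self, ref):
        ps = design_probe_set(ref, self._a_cpg(ref))
        orig, unmeth = ps.probes["orig"], ps.probes["uW"]
        for a, b in zip(orig, unmeth):
            if a == "C":
                assert b == "T"
            else:
                assert b == a

    def test_deterministic(self, ref):
        pos = self._a_cpg(ref)
        assert design_probe_set(ref, pos) == design_probe_set(ref, pos)

    def test_window_shifted_near_edge(self, ref):
        pos = ref.find("CG")
        ps = design_probe_set(ref, pos)
        assert ps.window_start == 0 if pos < 60 else ps.window_start > 0
        assert all(len(p) == 120 for p in ps.probes.values())

    def test_short_reference_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            design_probe_set("ACG" * 10, 1)

    def test_non_cpg_position_rejected(self, ref):
        pos = ref.find("T", 200)  # a T is never the C of a CpG
        with pytest.raises(ValueError, match="CpG"):
            design_probe_set(ref, pos)

    def test_fasta_record_ids(self, ref):
        ps = design_probe_set(ref, self._a_cpg(ref), cpg_id="cg007")
        ids = [name for name, _ in ps.to_fasta_records()]
        assert ids == [f"cg007_{s}" for s in PROBE_SUFFIXES]
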