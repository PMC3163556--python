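"""Expression preprocessing, the DEG-calling cascade, and DEG partition."""
import numpy as np
import pandas as pd
import pytest

from drugscout.errors import DesignError, FormatError
from drugscout.synthetic_fixtures import FixtureSpec, generate_expression
from drugscout.transcriptome import (
    ExpressionMatrix,
    GroupDesign,
    apply_fold_threshold,
    call_degs,
    partition_deg_lists,
    preprocess_matrix,
    read_design,
    read_matrix,
    read_presence,
)


def _matrix(values, genes=None, samples=None, presence=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    pres = None
    if presence is not None:
        pres = pd.DataFrame(presence, index=genes, columns=samples)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), presence=pres
    )


class TestPreprocess:
    def test_flooring(self):
        m = preprocess_matrix(_matrix([[7, 40], [10, 160]]))
        assert m.values.iloc[0, 0] == pytest.approx(np.log2(10))
        assert m.values.iloc[1, 1] == pytest.approx(np.log2(160))
        assert m.log2

    def test_all_absent_gene_removed_partial_retained(self):
        m = _matrix(
            [[20, 20], [20, 20], [20, 20]],
            presence=[["A", "A"], ["A", "P"], ["P", "P"]],
        )
        out = preprocess_matrix(m)
        assert out.genes == ["g1", "g2"]

    def test_no_presence_calls_only_log2(self):
        m = preprocess_matrix(_matrix([[16, 32]]))
        assert list(m.values.iloc[0]) == [4.0, 5.0]

    def test_non_numeric_cell_reports_coordinates(self):
        df = pd.DataFrame({"s0": [1.0, "oops"]}, index=["g0", "g1"])
        with pytest.raises(FormatError, match="g1.*s0"):
            preprocess_matrix(ExpressionMatrix(values=df))


def _simulate(n_genes=60, n_planted=6, effect=2.0, sigma=0.25, n=5, seed=0):
    """Two-group log-normal simulator used as the calling oracle's truth."""
    rng = np.random.default_rng(seed)
    base = rng.normal(8, 1.5, size=n_genes)
    log2 = np.tile(base[:, None], (1, 2 * n))
    log2[:n_planted, n:] += effect
    log2 += rng.normal(0, sigma, size=log2.shape)
    samples = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
    m = ExpressionMatrix(
        values=pd.DataFrame(
            np.power(2.0, log2),
            index=[f"g{i}" for i in range(n_genes)],
            columns=samples,
        )
    )
    design = GroupDesign(
        groups={s: ("T" if s.startswith("t") else "C") for s in samples},
        contrast=("T", "C"),
    )
    return preprocess_matrix(m), design


class TestCallDegs:
    def test_planted_truth_recovery(self):
        """Planted 4-fold effects survive the full cascade; background
        genes do not."""
        m, d = _simulate(n_genes=200, n_planted=20, seed=7)
        records = call_degs(m, d)
        up, down = apply_fold_threshold(records)
        called = {r.gene for r in up} | {r.gene for r in down}
        planted = {f"g{i}" for i in range(20)}
        assert len(called & planted) >= 18
        assert len(called - planted) <= 2

    def test_effect_size_recovery(self):
        """Estimated log2 ratios track the planted effect closely."""
        m, d = _simulate(n_genes=100, n_planted=100, effect=1.5, seed=3)
        records = call_degs(m, d)
        errors = [abs(r.log2_ratio - 1.5) for r in records]
        assert np.mean(errors) < 0.2

    def test_zero_variance_gene_gets_p_one(self):
        m = _matrix([[32] * 6], samples=[f"s{i}" for i in range(6)])
        design = GroupDesign(
            groups={f"s{i}": ("T" if i < 3 else "C") for i in range(6)},
            contrast=("T", "C"),
        )
        rec = call_degs(preprocess_matrix(m), design)[0]
        assert rec.p_class == 1.0
        assert not rec.significant

    def test_small_group_rejected(self):
        m = _matrix([[1, 2, 3]], samples=["a", "b", "c"])
        design = GroupDesign(groups={"a": "T", "b": "C", "c": "C"}, contrast=("T", "C"))
        with pytest.raises(DesignError):
            call_degs(preprocess_matrix(m), design)

    def test_invariant_to_row_and_column_order(self):
        m, d = _simulate(n_genes=40, n_planted=5, seed=11)
        records = {r.gene: r for r in call_degs(m, d)}
        rng = np.random.default_rng(1)
        shuffled = ExpressionMatrix(
            values=m.values.iloc[
                rng.permutation(len(m.genes)), rng.permutation(len(m.samples))
            ],
            log2=True,
        )
        for r in call_degs(shuffled, d):
            ref = records[r.gene]
            assert r.p_class == pytest.approx(ref.p_class)
            assert r.log2_ratio == pytest.approx(ref.log2_ratio)

    def test_filter_cascade_monotone(self):
        """Relaxing any threshold never removes a previously called DEG."""
        m, d = _simulate(n_genes=120, n_planted=15, effect=1.3, sigma=0.5, seed=5)
        strict = call_degs(m, d, alpha=0.01, fdr=0.05, t_alpha=0.01)
        relaxed = call_degs(m, d, alpha=0.05, fdr=0.25, t_alpha=0.05)
        strict_called = {
            r.gene for lst in apply_fold_threshold(strict, log2_cut=1.1) for r in lst
        }
        relaxed_called = {
            r.gene for lst in apply_fold_threshold(relaxed, log2_cut=0.5) for r in lst
        }
        assert relaxed_called >= strict_called

    def test_type_one_error_calibration(self):
        """Null data: the mean fraction of genes at p < 0.01 sits near 0.01."""
        fractions = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            log2 = rng.normal(8, 0.25, size=(200, 10))
            m = ExpressionMatrix(
                values=pd.DataFrame(
                    log2,
                    index=[f"g{i}" for i in range(200)],
                    columns=[f"s{i}" for i in range(10)],
                ),
                log2=True,
            )
            d = GroupDesign(
                groups={f"s{i}": ("T" if i < 5 else "C") for i in range(10)},
                contrast=("T", "C"),
            )
            ps = np.array([r.p_class for r in call_degs(m, d)])
            fractions.append((ps < 0.01).mean())
        assert 0.005 <= np.mean(fractions) <= 0.015


class TestFoldThreshold:
    def _rec(self, lr, sig=True):
        from drugscout.transcriptome import DEGRecord

        return DEGRecord(
            gene="g", log2_ratio=lr, p_class=0.001, fdr_pass=sig, p_t=0.001,
            direction="down" if lr < 0 else "up", passes_fold=abs(lr) >= 1.1,
            significant=sig,
        )

    def test_above_cut_retained_up(self):
        up, down = apply_fold_threshold([self._rec(1.2)])
        assert len(up) == 1 and not down

    def test_below_cut_dropped(self):
        up, down = apply_fold_threshold([self._rec(1.0)])
        assert not up and not down

    def test_boundary_inclusive_down(self):
        up, down = apply_fold_threshold([self._rec(-1.1)])
        assert not up and len(down) == 1

    def test_insignificant_dropped_despite_fold(self):
        up, down = apply_fold_threshold([self._rec(3.0, sig=False)])
        assert not up and not down


class TestDEGPartition:
    def test_worked_example(self):
        part = partition_deg_lists({"A": {"g1", "g2"}, "B": {"g2", "g3"}, "C": {"g2"}})
        assert part.common == {"g2"}
        assert part.unique["A"] == {"g1"}
        assert part.unique["B"] == {"g3"}

    def test_empty_list_allowed(self):
        part = partition_deg_lists({"A": {"g1"}, "B": set()})
        assert part.unique["B"] == set()
        assert part.unique["A"] == {"g1"}


class TestGeneratorRoundTrip:
    def test_generated_study_parses_and_calls(self, tmp_path):
        """Matrix, presence and design written by the generator flow through
        preprocessing and DEG calling; planted genes dominate the calls."""
        spec = FixtureSpec(seed=7)
        truth = generate_expression(spec, tmp_path, drugs=["T"])
        m = ExpressionMatrix(
            values=read_matrix(tmp_path / "expression.tsv"),
            presence=read_presence(tmp_path / "presence.tsv"),
        )
        pre = preprocess_matrix(m)
        for decoy in truth["absent_decoys"]:
            assert decoy not in pre.genes
        d = read_design(tmp_path / "design.tsv", ("T", "CTRL"))
        up, down = apply_fold_threshold(call_degs(pre, d))
        called = {r.gene for r in up} | {r.gene for r in down}
        planted = set(truth["planted"]["T"])
        assert len(called & planted) >= 0.9 * len(planted)
        assert len(called - planted) <= 2
        for r in up:
            if r.gene in planted:
                assert truth["planted"]["T"][r.gene] == "up"
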