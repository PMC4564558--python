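"""Directional expression enrichment against a measured background."""

import numpy as np
import pytest

from genesect import (
    DirectionalExpressionSample,
    FunctionalGeneSet,
    GeneUniverse,
    crosstab_against_reference,
    hypergeom_tail,
    run_directional_analysis,
)

def _universe(n):
    return GeneUniverse.from_symbols([f"G{i:04d}" for i in range(n)], label="background")


def _genes(indices):
    return frozenset(f"G{i:04d}" for i in indices)


@pytest.fixture
def background():
    return _universe(1000)


@pytest.fixture
def sample(background):
    # 30 upregulated genes, 20 of which lie in a 100-gene set
    return DirectionalExpressionSample(
        label="pm", up=_genes(range(30)), down=_genes(range(500, 540)), background=background,
    )


@pytest.fixture
def sets():
    return {
        "S": FunctionalGeneSet.from_symbols("S", [f"G{i:04d}" for i in list(range(20)) + list(range(100, 180))]),
        "T": FunctionalGeneSet.from_symbols("T", [f"G{i:04d}" for i in range(800, 900)]),
    }


class TestDirectional:
    def test_planted_up_enrichment(self, sample, sets):
        up, down = run_directional_analysis(sample, sets)
        row = up.row("S")
        assert row.observed == 20
        assert row.expected == pytest.approx(3.0)
        assert row.rf == pytest.approx(20 / 3, abs=0.01)
        assert row.p_nominal < 1e-10
        assert row.universe_size == 1000
        assert up.provenance["direction"] == "up"

    def test_sets_restricted_to_background_before_sizing(self, sample):
        # 50 of the set's 100 genes are off the measured background
        wide = FunctionalGeneSet.from_symbols(
            "W", [f"G{i:04d}" for i in range(950, 1050)]
        )
        up, _ = run_directional_analysis(sample, {"W": wide})
        assert up.row("W").set_size == 50

    def test_directions_are_independent(self, background, sets):
        base = DirectionalExpressionSample(
            label="pm", up=_genes(range(30)), down=_genes(range(500, 540)), background=background,
        )
        permuted = DirectionalExpressionSample(
            label="pm", up=_genes(range(30)), down=_genes(range(700, 740)), background=background,
        )
        up1, _ = run_directional_analysis(base, sets)
        up2, _ = run_directional_analysis(permuted, sets)
        assert up1.rows == up2.rows

    def test_disjoint_up_list_all_null(self, background, sets):
        sample = DirectionalExpressionSample(
            label="pm", up=_genes(range(300, 330)), down=_genes(range(500, 540)), background=background,
        )
        up, _ = run_directional_analysis(sample, sets)
        assert all(r.p_nominal == 1.0 for r in up.rows)

    def test_overlapping_directions_rejected(self, background):
        with pytest.raises(ValueError, match="both directions"):
            DirectionalExpressionSample(
                label="pm", up=_genes(range(10)), down=_genes(range(5, 15)), background=background,
            )

    def test_genes_outside_background_rejected(self, background):
        with pytest.raises(ValueError, match="outside"):
            DirectionalExpressionSample(
                label="pm", up=frozenset({"NOT_MEASURED"}), down=_genes(range(5)), background=background,
            )

    def test_null_calibration_is_conservative(self, background, sets):
        # with no planted signal the one-sided exact test rejects at most at
        # its nominal rate (plus Monte-Carlo slack)
        rng = np.random.default_rng(99)
        R, rejections, rows = 400, 0, 0
        down = _genes(range(500, 540))
        pool = np.concatenate([np.arange(0, 500), np.arange(540, 1000)])
        for _ in range(R):
            up = _genes(rng.choice(pool, size=30, replace=False))
            s = DirectionalExpressionSample(label="pm", up=up, down=down, background=background)
            table, _ = run_directional_analysis(s, sets)
            rejections += sum(r.p_nominal <= 0.05 for r in table.rows)
            rows += len(table)
        rate = rejections / rows
        assert rate <= 0.05 + 3 * (0.05 * 0.95 / rows) ** 0.5


class TestCrosstab:
    def test_fraction_arithmetic(self):
        universe = _universe(2000)
        reference = FunctionalGeneSet.from_symbols("ref", [f"G{i:04d}" for i in range(476)])
        probe = FunctionalGeneSet.from_symbols("P", [f"G{i:04d}" for i in range(205)])
        rows = crosstab_against_reference(reference, {"P": probe}, universe)
        assert rows[0].overlap == 205
        assert rows[0].fraction_pct == pytest.approx(100 * 205 / 476, abs=0.01)

    def test_probe_equal_to_universe_is_total(self):
        universe = _universe(500)
        whole = FunctionalGeneSet(label="U", members=universe.members)
        rows = crosstab_against_reference(
            FunctionalGeneSet.from_symbols("ref", [f"G{i:04d}" for i in range(100)]),
            {"U": whole}, universe,
        )
        assert rows[0].fraction_pct == 100.0

    def test_planted_crosstab_reaches_floor_regime(self):
        # a 476-gene reference with 43% membership in a 3211-gene category of
        # a 21,000-gene universe: overlap 205, far beyond the display floor
        p = hypergeom_tail(205, 3211, 476, 21000)
        universe = GeneUniverse.from_size(21000)
        assert p <= 2.2e-16
        # same computation through the crosstab on explicit synthetic genes
        big = _universe(21000)
        ref_members = [f"G{i:04d}" for i in range(205)] + [f"G{i:05d}" for i in range(10000, 10271)]
        nd_members = [f"G{i:04d}" for i in range(205)] + [f"G{i:05d}" for i in range(14000, 17006)]
        rows = crosstab_against_reference(
            FunctionalGeneSet.from_symbols("ref", ref_members),
            {"ND": FunctionalGeneSet.from_symbols("ND", nd_members)},
            big,
        )
        assert rows[0].reference_size == 476
        assert rows[0].fraction_pct == pytest.approx(43.07, abs=0.01)
        assert rows[0].p_value <= 2.2e-16

    def test_empty_reference_rejected(self):
        universe = _universe(100)
        with pytest.raises(ValueError):
            crosstab_against_reference(
                FunctionalGeneSet(label="ref", members=frozenset({"NOT_THERE"})),
                {"P": FunctionalGeneSet.from_symbols("P", [f"G{i:04d}" for i in range(5)])},
                universe,
            )
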