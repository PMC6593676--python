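"""SNP filters: per-rule thresholds, conservation, idempotence, PAR inference."""

import numpy as np
import pytest

from gbsex import (
    AlleleDepthMatrix,
    ConfigError,
    FilterConfig,
    InputError,
    SnpTable,
    call_genotypes,
    filter_x_snps,
    filter_y_snps,
    infer_par_boundary,
    make_gender_series,
    minor_allele_frequency,
    simulate,
    SimulationConfig,
)
from gbsex.filters import (
    REASON_FEMALE_MISSING,
    REASON_FEMALE_NONMISSING,
    REASON_MAF,
    REASON_MALE_HET,
    REASON_PAR,
)


def _cohort(n_males, n_females, columns, chrom="X", positions=None):
    """Build a 1-SNP-per-column dataset from (ref, alt) cell lists.

    ``columns`` is a list of dicts snp_id -> list of (ref, alt) per sample,
    males first.
    """
    samples = [f"M{i}" for i in range(n_males)] + [f"F{i}" for i in range(n_females)]
    snp_ids = list(columns)
    ref = np.array([[columns[s][i][0] for s in snp_ids] for i in range(len(samples))])
    alt = np.array([[columns[s][i][1] for s in snp_ids] for i in range(len(samples))])
    adm = AlleleDepthMatrix(samples, snp_ids, ref, alt)
    if positions is None:
        positions = [1_000_000 * (j + 1) for j in range(len(snp_ids))]
    snps = SnpTable.from_arrays(snp_ids, [chrom] * len(snp_ids), positions)
    genders = make_gender_series(samples, ["M"] * n_males + ["F"] * n_females)
    return adm, snps, genders


class TestXRules:
    def test_par_position_discarded(self):
        # one X SNP beyond 170 Mb, otherwise clean
        cells = [(4, 0)] * 2 + [(2, 2)] * 2
        adm, snps, genders = _cohort(2, 2, {"s": cells}, positions=[171_000_000])
        gm = call_genotypes(adm)
        out, rep = filter_x_snps(gm, adm, snps, genders)
        assert rep.reasons_by_snp == {"s": (REASON_PAR,)}

    def test_male_het_at_threshold_discarded(self):
        # 10 males all non-missing, exactly 1 HET (10% >= 10%)
        cells = [(2, 2)] + [(4, 0)] * 9 + [(2, 2)] * 10
        adm, snps, genders = _cohort(10, 10, {"s": cells})
        out, rep = filter_x_snps(call_genotypes(adm), adm, snps, genders)
        assert rep.reasons_by_snp["s"] == (REASON_MALE_HET,)

    def test_male_het_below_threshold_kept(self):
        # 1 HET among 11 non-missing males (~9%) survives
        cells = [(2, 2)] + [(4, 0)] * 10 + [(2, 2)] * 10
        adm, snps, genders = _cohort(11, 10, {"s": cells})
        out, rep = filter_x_snps(call_genotypes(adm), adm, snps, genders)
        assert rep.n_kept == 1

    def test_female_missing_at_threshold_discarded(self):
        cells = [(4, 0)] * 10 + [(0, 0)] * 1 + [(2, 2)] * 9
        adm, snps, genders = _cohort(10, 10, {"s": cells})
        out, rep = filter_x_snps(call_genotypes(adm), adm, snps, genders)
        assert rep.reasons_by_snp["s"] == (REASON_FEMALE_MISSING,)

    def test_clean_snp_kept(self):
        cells = [(4, 0)] * 10 + [(2, 2)] * 10
        adm, snps, genders = _cohort(10, 10, {"s": cells})
        out, rep = filter_x_snps(call_genotypes(adm), adm, snps, genders)
        assert rep.n_kept == 1 and rep.reasons_by_snp == {}

    def test_requires_both_sexes(self):
        cells = [(4, 0)] * 4
        adm, snps, _ = _cohort(4, 0, {"s": cells})
        genders = make_gender_series(adm.sample_ids, ["M"] * 4)
        with pytest.raises(ConfigError, match="male"):
            filter_x_snps(call_genotypes(adm), adm, snps, genders)


class TestYRules:
    def test_female_nonmissing_at_threshold_discarded(self):
        # 20 females, exactly 1 with a called genotype (5% >= 5%)
        cells = [(4, 0)] * 5 + [(0, 4)] * 5 + [(1, 0)] + [(0, 0)] * 19
        adm, snps, genders = _cohort(10, 20, {"s": cells}, chrom="Y")
        out, rep = filter_y_snps(call_genotypes(adm), adm, snps, genders)
        assert rep.reasons_by_snp["s"] == (REASON_FEMALE_NONMISSING,)

    def test_clean_y_kept(self):
        cells = [(4, 0)] * 5 + [(0, 4)] * 5 + [(0, 0)] * 20
        adm, snps, genders = _cohort(10, 20, {"s": cells}, chrom="Y")
        out, rep = filter_y_snps(call_genotypes(adm), adm, snps, genders)
        assert rep.n_kept == 1

    def test_male_het_at_half_discarded(self):
        cells = [(2, 2)] * 5 + [(4, 0)] * 5 + [(0, 0)] * 20
        adm, snps, genders = _cohort(10, 20, {"s": cells}, chrom="Y")
        out, rep = filter_y_snps(call_genotypes(adm), adm, snps, genders)
        assert rep.reasons_by_snp["s"] == (REASON_MALE_HET,)

    def test_y_in_par_position_not_par_filtered(self):
        # Y SNPs are never position-filtered; a clean Y SNP at 171 Mb stays
        cells = [(4, 0)] * 5 + [(0, 4)] * 5 + [(0, 0)] * 20
        adm, snps, genders = _cohort(10, 20, {"s": cells}, chrom="Y", positions=[171_000_000])
        out, rep = filter_y_snps(call_genotypes(adm), adm, snps, genders)
        assert rep.n_kept == 1


class TestMaf:
    def test_symmetric_counts(self):
        adm = AlleleDepthMatrix(["a", "b"], ["s"], [[25], [25]], [[30], [20]])
        assert minor_allele_frequency(adm, "s") == pytest.approx(0.5)

    def test_rare_allele(self):
        adm = AlleleDepthMatrix(["a"], ["s"], [[99]], [[1]])
        assert minor_allele_frequency(adm, "s") == pytest.approx(0.01)

    def test_boundary_is_kept(self):
        # MAF exactly 0.015: "less than" is strict, so the SNP survives
        cells = [(4, 0)] * 10 + [(2, 2)] * 10  # clean otherwise
        adm, snps, genders = _cohort(10, 10, {"s": cells})
        # overwrite counts to 197 ref / 3 alt pooled => exactly 0.015
        adm.ref_count[:, 0] = [20] * 9 + [17] + [0] * 10
        adm.alt_count[:, 0] = [0] * 9 + [3] + [0] * 10
        assert minor_allele_frequency(adm, "s") == pytest.approx(0.015)
        # females all missing here, so disable the missingness rule to
        # isolate the MAF boundary behaviour
        cfg = FilterConfig(x_female_missing_max=1.0, x_male_het_max=1.0)
        _, rep = filter_x_snps(call_genotypes(adm), adm, snps, genders, cfg)
        assert REASON_MAF not in rep.reasons_by_snp.get("s", ())

    def test_zero_depth_undefined(self):
        adm = AlleleDepthMatrix(["a"], ["s"], [[0]], [[0]])
        with pytest.raises(InputError, match="undefined"):
            minor_allele_frequency(adm, "s")

    def test_low_maf_discarded_on_both_chromosomes(self):
        x_cells = [(4, 0)] * 10 + [(4, 0)] * 9 + [(3, 1)]
        adm, snps, genders = _cohort(10, 10, {"s": x_cells})
        out, rep = filter_x_snps(call_genotypes(adm), adm, snps, genders)
        assert rep.reasons_by_snp["s"] == (REASON_MAF,)
        y_cells = [(7, 0)] * 9 + [(6, 1)] + [(0, 0)] * 10
        adm, snps, genders = _cohort(10, 10, {"s": y_cells}, chrom="Y")
        out, rep = filter_y_snps(call_genotypes(adm), adm, snps, genders)
        assert rep.reasons_by_snp["s"] == (REASON_MAF,)


class TestFixtureAndInvariants:
    def test_one_discard_per_rule(self, filter_fixture):
        fx = filter_fixture
        gm = call_genotypes(fx.adm)
        snps, xr = filter_x_snps(gm, fx.adm, fx.snps, fx.genders)
        snps, yr = filter_y_snps(gm, fx.adm, snps, fx.genders)
        assert {k: v[0] for k, v in xr.reasons_by_snp.items()} == fx.expected_x_reasons
        assert {k: v[0] for k, v in yr.reasons_by_snp.items()} == fx.expected_y_reasons
        assert tuple(snps.ids("X", kept=True)) == fx.kept_x
        assert tuple(snps.ids("Y", kept=True)) == fx.kept_y

    def test_counts_conserved(self, filter_fixture):
        fx = filter_fixture
        gm = call_genotypes(fx.adm)
        _, xr = filter_x_snps(gm, fx.adm, fx.snps, fx.genders)
        _, yr = filter_y_snps(gm, fx.adm, fx.snps, fx.genders)
        assert xr.n_kept + sum(xr.discard_counts.values()) == xr.n_input
        assert yr.n_kept + sum(yr.discard_counts.values()) == yr.n_input

    def test_idempotent(self, filter_fixture):
        fx = filter_fixture
        gm = call_genotypes(fx.adm)
        once, _ = filter_x_snps(gm, fx.adm, fx.snps, fx.genders)
        once, _ = filter_y_snps(gm, fx.adm, once, fx.genders)
        twice, xr2 = filter_x_snps(gm, fx.adm, once, fx.genders)
        twice, yr2 = filter_y_snps(gm, fx.adm, twice, fx.genders)
        assert xr2.reasons_by_snp == {} and yr2.reasons_by_snp == {}
        assert list(twice.ids(kept=True)) == list(once.ids(kept=True))

    @pytest.mark.parametrize(
        "loose",
        [
            {"x_male_het_max": 0.5},
            {"x_female_missing_max": 0.5},
            {"y_female_nonmissing_max": 0.5},
            {"y_male_het_max": 0.9},
            {"maf_min": 0.0},
            {"par_start_bp": 180_000_000},
        ],
    )
    def test_loosening_never_discards_more(self, filter_fixture, loose):
        fx = filter_fixture
        gm = call_genotypes(fx.adm)
        base = FilterConfig()
        loose_cfg = FilterConfig(**loose)
        for fn in (filter_x_snps, filter_y_snps):
            _, tight_rep = fn(gm, fx.adm, fx.snps, fx.genders, base)
            _, loose_rep = fn(gm, fx.adm, fx.snps, fx.genders, loose_cfg)
            assert loose_rep.n_kept >= tight_rep.n_kept


class TestParBoundary:
    @staticmethod
    def _brute_force(het_prop, pos, window_bp, thr):
        """Independent window scan: last run of above-threshold windows."""
        win = (np.asarray(pos) - 1) // window_bp
        n_win = int(win.max()) + 1
        means = []
        for w in range(n_win):
            vals = [h for h, wi in zip(het_prop, win) if wi == w and not np.isnan(h)]
            means.append(np.mean(vals) if vals else np.nan)
        best = None
        for w in range(n_win - 1, -1, -1):
            if np.isnan(means[w]):
                continue
            if means[w] > thr:
                best = w
            else:
                break
        return None if best is None else best * window_bp + 1

    def test_changepoint_recovered_within_one_window(self):
        cfg = SimulationConfig(
            n_males=150, n_females=30, m_x=400, m_y=4, depth_mean=3.0,
            par_snp_fraction=0.15, per_read_error=0.002, seed=5,
        )
        ds = simulate(cfg)
        gm = call_genotypes(ds.adm)
        boundary = infer_par_boundary(gm, ds.snps, ds.recorded)
        assert boundary is not None
        assert abs(boundary - 170_000_000) <= 5_000_000

    def test_matches_brute_force_oracle(self):
        cfg = SimulationConfig(
            n_males=80, n_females=20, m_x=300, m_y=4, depth_mean=3.0,
            par_snp_fraction=0.2, per_read_error=0.0, seed=9,
        )
        ds = simulate(cfg)
        gm = call_genotypes(ds.adm)
        from gbsex.containers import Genotype

        x_ids = ds.snps.ids("X")
        cols = gm.snp_indices(x_ids)
        males = (ds.recorded.reindex(gm.sample_ids) == "M").to_numpy()
        calls = gm.call[np.ix_(males, cols)]
        nonmiss = (calls != Genotype.MISSING).sum(axis=0).astype(float)
        het = (calls == Genotype.HET).sum(axis=0)
        with np.errstate(invalid="ignore"):
            prop = np.where(nonmiss > 0, het / np.where(nonmiss > 0, nonmiss, 1), np.nan)
        expected = self._brute_force(prop, ds.snps.position(x_ids), 5_000_000, 0.1)
        assert infer_par_boundary(gm, ds.snps, ds.recorded) == expected

    def test_uniform_zero_het_finds_nothing(self):
        cells = {f"s{j}": [(4, 0)] * 5 + [(2, 2)] * 5 for j in range(4)}
        adm, snps, genders = _cohort(5, 5, cells, positions=[1, 6_000_000, 11_000_000, 16_000_000])
        assert infer_par_boundary(call_genotypes(adm), snps, genders) is None

    def test_uniform_high_het_returns_first_window(self):
        cells = {f"s{j}": [(2, 2)] * 10 for j in range(4)}
        adm, snps, genders = _cohort(5, 5, cells, positions=[1, 6_000_000, 11_000_000, 16_000_000])
        assert infer_par_boundary(call_genotypes(adm), snps, genders) == 1

    def test_empty_x_set_is_input_error(self):
        cells = {"s": [(4, 0)] * 10}
        adm, snps, genders = _cohort(5, 5, cells, chrom="Y")
        with pytest.raises(InputError):
            infer_par_boundary(call_genotypes(adm), snps, genders)
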