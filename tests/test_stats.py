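"""Statistical layer: t-tests, FDR, repeated-measures ANOVA, LSD post-hocs.

Worked values come from the published group-level table of mismatch-response
t-tests (printed M, SD per electrode at n=26, with its BH-FDR column); the
ANOVA is validated against an explicit brute-force sum-of-squares oracle and
against pingouin for designs it supports.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from segspeech import stats as st

# Printed mismatch table: channel -> (M, SD, t, p, p_fdr), n = 26.
TABLE_FLAT_300 = {
    "Fp1": (-0.07, 2.1, -0.2, 0.87, 0.94), "Fp2": (-0.19, 2.2, -0.4, 0.66, 0.94),
    "F4": (0.06, 1.9, 0.1, 0.88, 0.94), "Fz": (0.03, 1.8, 0.1, 0.94, 0.94),
    "F3": (-0.38, 2.3, -0.8, 0.42, 0.94), "T7": (-0.98, 2.1, -2.3, 0.02, 0.20),
    "C3": (-0.34, 2.6, -0.7, 0.52, 0.94), "Cz": (-0.21, 3.1, -0.3, 0.74, 0.94),
    "C4": (-0.04, 2.3, -0.1, 0.94, 0.94), "T8": (0.66, 2.2, 1.6, 0.13, 0.65),
}
TABLE_FLAT_800 = {
    "Fp1": (-0.13, 1.4, -0.5, 0.64, 0.88), "Fp2": (-0.24, 1.1, -1.0, 0.31, 0.88),
    "F4": (-0.08, 1.3, -0.3, 0.76, 0.88), "Fz": (-0.07, 1.5, -0.2, 0.80, 0.88),
    "F3": (-0.17, 1.2, -0.7, 0.50, 0.88), "T7": (-0.47, 1.3, -1.9, 0.07, 0.70),
    "C3": (-0.21, 1.7, -0.6, 0.52, 0.88), "Cz": (-0.05, 1.8, -0.1, 0.89, 0.89),
    "C4": (0.12, 1.5, 0.4, 0.67, 0.88), "T8": (0.09, 1.1, 0.4, 0.70, 0.88),
}
TABLE_MEL_300 = {
    "Fp1": (1.27, 2.3, 2.9, 0.008, 0.07), "Fp2": (1.33, 2.8, 2.4, 0.02, 0.07),
    "F4": (1.13, 2.9, 1.9, 0.06, 0.10), "Fz": (1.06, 3.2, 1.7, 0.10, 0.14),
    "F3": (1.29, 3.0, 2.2, 0.03, 0.07), "T7": (0.77, 0.5, 1.6, 0.12, 0.15),
    "C3": (1.10, 2.7, 2.1, 0.04, 0.08), "Cz": (1.40, 3.2, 2.2, 0.03, 0.07),
    "C4": (0.69, 2.9, 1.2, 0.24, 0.26), "T8": (0.52, 0.6, 0.9, 0.39, 0.39),
}
TABLE_MEL_800 = {
    "Fp1": (1.49, 2.0, 3.8, 0.0008, 0.003), "Fp2": (1.53, 2.0, 3.9, 0.0006, 0.003),
    "F4": (1.17, 1.9, 3.1, 0.004, 0.01), "Fz": (1.15, 2.1, 2.8, 0.009, 0.01),
    "F3": (1.32, 2.3, 2.9, 0.007, 0.01), "T7": (0.48, 1.9, 1.3, 0.2, 0.20),
    "C3": (1.02, 2.0, 2.6, 0.01, 0.01), "Cz": (1.38, 1.9, 3.7, 0.001, 0.003),
    "C4": (0.86, 2.0, 2.2, 0.04, 0.05), "T8": (0.57, 1.7, 1.7, 0.10, 0.11),
}
N_TABLE = 26
# Rows whose printed SD is internally inconsistent with the printed t and d
# (typos in the source table: back-solving gives SD ~ 2.5 / 3.5).
TYPO_ROWS = {("mel300", "T7"), ("mel300", "T8")}
ALL_TABLES = {"flat300": TABLE_FLAT_300, "flat800": TABLE_FLAT_800,
              "mel300": TABLE_MEL_300, "mel800": TABLE_MEL_800}


def agrees_at_printed_precision(value: float, printed: float) -> bool:
    """True if truncating or rounding `value` to the printed number of
    decimals reproduces `printed` (the source table truncates)."""
    s = f"{printed}"
    decimals = len(s.split(".")[1]) if "." in s else 0
    scale = 10 ** decimals
    return (np.floor(value * scale) / scale == pytest.approx(printed)
            or round(value, decimals) == pytest.approx(printed))


class TestOneSampleT:
    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.4, 1.0, size=20)
        res = st.one_sample_t(x)
        ref = sps.ttest_1samp(x, 0.0)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df == 19
        assert res.cohens_d == pytest.approx(x.mean() / x.std(ddof=1))

    def test_symmetric_sample_t_zero(self):
        res = st.one_sample_t([-2.0, -1.0, 1.0, 2.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_identically_zero_sample(self):
        res = st.one_sample_t([0.0, 0.0, 0.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_zero_variance_nonzero_mean_flagged(self):
        with pytest.raises(st.StatsError):
            st.one_sample_t([1.0, 1.0, 1.0])

    @pytest.mark.parametrize("m,sd,printed_t", [(1.49, 2.0, 3.8),
                                                (1.15, 2.1, 2.8)])
    def test_printed_worked_examples(self, m, sd, printed_t):
        res = st.summary_t(m, sd, N_TABLE)
        assert round(res.t, 1) == pytest.approx(printed_t)

    def test_t_identity_across_printed_table(self):
        """t = M/(SD/sqrt(26)) reproduces every printed t once the rounding of
        the printed M (+-0.005) and SD (+-0.05) is propagated; the two typo
        rows are excluded (their printed SDs contradict their own t and d)."""
        for tbl_name, tbl in ALL_TABLES.items():
            for ch, (m, sd, t_printed, _, _) in tbl.items():
                if (tbl_name, ch) in TYPO_ROWS:
                    continue
                corners = [
                    (m + dm) / ((sd + dsd) / np.sqrt(N_TABLE))
                    for dm in (-0.005, 0.005) for dsd in (-0.05, 0.05)]
                lo, hi = min(corners) - 0.05, max(corners) + 0.05
                assert lo <= t_printed <= hi, (tbl_name, ch)


class TestFdrBH:
    @pytest.mark.parametrize("tbl_name", list(ALL_TABLES))
    def test_reproduces_printed_fdr_columns(self, tbl_name):
        tbl = ALL_TABLES[tbl_name]
        raw = [v[3] for v in tbl.values()]
        printed = [v[4] for v in tbl.values()]
        adj = st.fdr_bh(raw)
        for a, p in zip(adj, printed):
            assert agrees_at_printed_precision(a, p), (tbl_name, a, p)

    def test_single_p_unchanged(self):
        assert st.fdr_bh([0.04])[0] == pytest.approx(0.04)

    def test_all_equal_ps_unchanged(self):
        np.testing.assert_allclose(st.fdr_bh([0.2] * 6), 0.2)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=30)
        adj = st.fdr_bh(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(st.StatsError):
            st.fdr_bh([0.1, 1.2])


def brute_force_rm_anova(y):
    """Independent SS oracle for a fully-within design, subject axis first.

    Computes every effect's SS by explicit cell-mean inclusion-exclusion sums
    and the error SS from the subject-by-effect interaction, with plain
    Python loops.
    """
    n = y.shape[0]
    factors = list(range(1, y.ndim))
    out = {}
    for r in range(1, len(factors) + 1):
        for eff in itertools.combinations(factors, r):
            other = [f for f in factors if f not in eff]

            def cell_mean(fixed, subj=None):
                idx = []
                for ax in range(y.ndim):
                    if ax == 0:
                        idx.append(slice(None) if subj is None else subj)
                    elif ax in fixed:
                        idx.append(fixed[ax])
                    else:
                        idx.append(slice(None))
                block = y[tuple(idx)]
                return float(np.mean(block))

            ss_eff = 0.0
            ss_err = 0.0
            cells = itertools.product(*[range(y.shape[f]) for f in eff])
            scale_eff = n * int(np.prod([y.shape[f] for f in other])) \
                if other else n
            scale_err = int(np.prod([y.shape[f] for f in other])) if other else 1
            for cell in cells:
                fixed_full = dict(zip(eff, cell))
                est = 0.0
                for k in range(r + 1):
                    for sub in itertools.combinations(eff, k):
                        fixed = {f: fixed_full[f] for f in sub}
                        est += (-1) ** (r - k) * cell_mean(fixed)
                ss_eff += est ** 2
                for subj in range(n):
                    est_s = 0.0
                    for k in range(r + 1):
                        for sub in itertools.combinations(eff, k):
                            fixed = {f: fixed_full[f] for f in sub}
                            est_s += (-1) ** (r - k) * cell_mean(fixed, subj)
                    ss_err += (est_s - est) ** 2
            df1 = int(np.prod([y.shape[f] - 1 for f in eff]))
            df2 = df1 * (n - 1)
            out[eff] = (scale_eff * ss_eff, scale_err * ss_err, df1, df2)
    return out


def tidy_from_array(y, names):
    rows = []
    for idx in np.ndindex(*y.shape):
        row = {"subject": f"s{idx[0]}", "value": y[idx]}
        for name, lev in zip(names, idx[1:]):
            row[name] = f"{name}{lev}"
        rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    @pytest.mark.parametrize("shape,names", [
        ((4, 2, 2), ["A", "B"]),
        ((6, 3, 2), ["A", "B"]),
        ((5, 2, 3, 4), ["A", "B", "C"]),
    ])
    def test_matches_brute_force_oracle(self, shape, names):
        rng = np.random.default_rng(hash(tuple(shape)) % 2**31)
        y = rng.normal(size=shape)
        res = st.rm_anova(tidy_from_array(y, names), "value", names)
        oracle = brute_force_rm_anova(y)
        for eff, (ss_e, ss_r, df1, df2) in oracle.items():
            label = " * ".join(names[f - 1] for f in eff)
            row = res.loc[res["effect"] == label].iloc[0]
            f_oracle = (ss_e / df1) / (ss_r / df2)
            assert row["F"] == pytest.approx(f_oracle, rel=1e-9)
            assert row["ss_effect"] == pytest.approx(ss_e, rel=1e-9)
            assert row["ss_error"] == pytest.approx(ss_r, rel=1e-9)
            assert row["partial_eta_sq"] == pytest.approx(
                ss_e / (ss_e + ss_r), rel=1e-9)

    def test_matches_pingouin_two_factor(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        y = rng.normal(size=(8, 3, 2))
        df = tidy_from_array(y, ["A", "B"])
        mine = st.rm_anova(df, "value", ["A", "B"])
        ref = pg.rm_anova(data=df, dv="value", within=["A", "B"],
                          subject="subject", detailed=True)
        for eff in ("A", "B", "A * B"):
            m = mine.loc[mine["effect"] == eff].iloc[0]
            r = ref.loc[ref["Source"] == eff].iloc[0]
            assert m["F"] == pytest.approx(r["F"], rel=1e-9)
            assert m["epsilon_gg"] == pytest.approx(r["eps"], rel=1e-6)
            assert m["p_gg"] == pytest.approx(r["p_GG_corr"], rel=1e-6)

    def test_two_level_factor_equals_paired_t_squared(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=(2, 10))
        df = tidy_from_array(np.stack([a, b], axis=1), ["A"])
        res = st.rm_anova(df, "value", ["A"])
        t = st.paired_t(a, b)
        assert res["F"].iloc[0] == pytest.approx(t.t ** 2, rel=1e-9)
        assert res["epsilon_gg"].iloc[0] == 1.0

    def test_constant_factor_gives_zero_f(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(6, 1, 2))
        y = np.repeat(base, 3, axis=1)  # identical across A levels
        res = st.rm_anova(tidy_from_array(y, ["A", "B"]), "value", ["A", "B"])
        assert res.loc[res["effect"] == "A", "F"].iloc[0] == 0.0

    def test_missing_cells_rejected(self):
        df = tidy_from_array(np.zeros((3, 2)), ["A"]).iloc[:-1]
        with pytest.raises(st.StatsError):
            st.rm_anova(df, "value", ["A"])


class TestFisherLSD:
    def test_matches_brute_force_from_mse(self):
        means = {"a": 1.0, "b": 2.5, "c": 2.0}
        mse, dfe, n = 1.7, 12, 6
        res = st.fisher_lsd(means, mse, dfe, n)
        for _, row in res.iterrows():
            diff = means[row["a"]] - means[row["b"]]
            t = diff / np.sqrt(2 * mse / n)
            assert row["t"] == pytest.approx(t, rel=1e-12)
            assert row["p"] == pytest.approx(2 * sps.t.sf(abs(t), dfe),
                                             rel=1e-12)

    def test_equal_means_p_one(self):
        res = st.fisher_lsd({"a": 1.0, "b": 1.0}, 2.0, 10, 5)
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_single_cell_errors(self):
        with pytest.raises(st.StatsError):
            st.fisher_lsd({"a": 1.0}, 2.0, 10, 5)

    def test_unfitted_error_term_errors(self):
        with pytest.raises(st.StatsError):
            st.fisher_lsd({"a": 1.0, "b": 2.0}, np.nan, 10, 5)


class TestPhaseContrasts:
    @staticmethod
    def synth_amplitudes(seed, n_subjects=10, phase="test"):
        rng = np.random.default_rng(seed)
        channels = [f"ch{i}" for i in range(4)]
        rows = []
        for s in range(n_subjects):
            for cond in ("flat", "melodic"):
                if phase == "learning":
                    cells = [("1", 0.0), ("2", 1.0 if cond == "melodic" else 0.0)]
                    wins = [(200.0, 500.0)]
                else:
                    cells = [("legal", 0.0),
                             ("illegal", 1.2 if cond == "melodic" else 0.0)]
                    wins = [(300.0, 400.0), (800.0, 900.0)]
                for cell, eff in cells:
                    for lo, hi in wins:
                        for ch in channels:
                            rows.append({
                                "subject": f"s{s}", "condition": cond,
                                "phase": phase, "cell": cell, "channel": ch,
                                "win_lo_ms": lo, "win_hi_ms": hi,
                                "amplitude_uv": eff + rng.normal(0, 0.5),
                            })
        return pd.DataFrame(rows)

    def test_learning_contrast_structure(self):
        amps = self.synth_amplitudes(0, phase="learning")
        res = st.learning_contrast(amps)
        assert set(res.anova["effect"]) >= {"condition", "block",
                                            "condition * block"}
        inter = res.anova.loc[res.anova["effect"] == "condition * block"]
        assert inter["p_uncorrected"].iloc[0] < 0.05  # planted interaction
        mel = res.posthoc[res.posthoc["condition"] == "melodic"]
        assert mel["p"].iloc[0] < 0.05

    def test_learning_contrast_single_condition_errors(self):
        amps = self.synth_amplitudes(0, phase="learning")
        with pytest.raises(st.StatsError):
            st.learning_contrast(amps[amps["condition"] == "flat"])

    def test_test_phase_contrast_detects_planted_mmr(self):
        amps = self.synth_amplitudes(1)
        res = st.test_phase_contrast(amps, electrodes=[f"ch{i}"
                                                       for i in range(4)])
        tt = res.ttests
        mel = tt[tt["condition"] == "melodic"]
        flat = tt[tt["condition"] == "flat"]
        assert (mel["p_fdr"] < 0.05).all()
        assert (flat["p_fdr"] > 0.05).all()
        anova_mel = res.anovas[(res.anovas["condition"] == "melodic")
                               & (res.anovas["effect"] == "item_type")]
        assert (anova_mel["p_uncorrected"] < 0.01).all()
        assert not res.condition_anovas.empty

    def test_type_one_error_calibrated_under_null(self):
        """Per-electrode one-sample t at alpha=0.05 rejects ~5% of null
        difference waveforms (2000 simulated subject samples at n=26)."""
        rng = np.random.default_rng(20)
        rejections = 0
        n_sims = 2000
        for _ in range(n_sims):
            res = st.one_sample_t(rng.normal(0.0, 1.5, size=26))
            rejections += res.p < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_zero_difference_gives_zero_t(self):
        amps = self.synth_amplitudes(2)
        amps["amplitude_uv"] = 0.0
        res = st.test_phase_contrast(amps, electrodes=[f"ch{i}"
                                                       for i in range(4)])
        assert (res.ttests["t"] == 0.0).all()
        assert (res.ttests["p"] == 1.0).all()
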