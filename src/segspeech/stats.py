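"""Statistical layer: repeated-measures ANOVA with Greenhouse–Geisser
correction and partial η², one-sample t-tests, Cohen's d, Benjamini–Hochberg
FDR, and Fisher LSD post-hocs, plus the two phase-level analyses built from
them (learning block dynamics; mismatch-response tests)."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as _la
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

# Electrodes entering the per-electrode mismatch t-tests (the fronto-central /
# temporal row set); ANOVAs use all 16 scalp channels.
TEST_T_ELECTRODES = ("Fp1", "Fp2", "F4", "Fz", "F3", "T7", "C3", "Cz", "C4", "T8")


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# t-tests and FDR
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    m: float
    sd: float
    n: int
    t: float
    df: int
    p: float
    cohens_d: float
    p_fdr: float | None = None


def one_sample_t(values: Sequence[float]) -> TTestResult:
    """Two-tailed one-sample Student's t against zero; d = M/SD."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise StatsError("need at least 2 observations")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        if m == 0:  # identically-zero sample: no evidence either way
            return TTestResult(m=0.0, sd=0.0, n=n, t=0.0, df=n - 1, p=1.0,
                               cohens_d=0.0)
        raise StatsError("zero variance with nonzero mean: t undefined")
    t = m / (sd / np.sqrt(n))
    p = 2.0 * _sps.t.sf(abs(t), n - 1)
    return TTestResult(m=m, sd=sd, n=n, t=float(t), df=n - 1, p=float(p),
                       cohens_d=m / sd)


def summary_t(m: float, sd: float, n: int) -> TTestResult:
    """One-sample t against zero from summary statistics (t = M/(SD/√n))."""
    if n < 2 or sd <= 0:
        raise StatsError("invalid summary statistics")
    t = m / (sd / np.sqrt(n))
    p = 2.0 * _sps.t.sf(abs(t), n - 1)
    return TTestResult(m=m, sd=sd, n=n, t=float(t), df=n - 1, p=float(p),
                       cohens_d=m / sd)


def fdr_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return one_sample_t(d)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (fully within-subject, balanced)
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels−1) × levels matrix with orthonormal rows, each orthogonal to
    the unit vector (Helmert basis)."""
    return _la.helmert(levels, full=False)


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the n × d matrix of orthonormalised
    contrast scores for one effect."""
    d = scores.shape[1]
    if d <= 1:
        return 1.0
    s = np.cov(scores, rowvar=False)
    denom = d * np.sum(s * s)
    if denom == 0:
        return 1.0
    eps = np.trace(s) ** 2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def rm_anova(data: pd.DataFrame, dv: str, within: Sequence[str],
             subject: str = "subject") -> pd.DataFrame:
    """Repeated-measures ANOVA for a complete, balanced within-subject design
    with any number of within factors.

    Each effect is tested against its own subject-by-effect interaction error
    term. Reports F, uncorrected and Greenhouse–Geisser-corrected p (GG is
    applied whenever an effect carries more than 1 numerator df, i.e. any
    involved factor has more than 2 levels), epsilon, and partial η² =
    SS_effect / (SS_effect + SS_error).
    """
    within = list(within)
    subjects = data[subject].unique()
    n = len(subjects)
    if n < 2:
        raise StatsError("need at least 2 subjects")
    levels = {f: list(pd.unique(data[f])) for f in within}
    shape = [n] + [len(levels[f]) for f in within]
    counts = data.groupby([subject, *within], sort=False)[dv].count()
    if len(counts) != np.prod(shape) or counts.nunique() != 1:
        raise StatsError("design must be complete and balanced "
                         "(one or equal replicates per subject/cell)")
    # Cell means per subject in a dense array, subject axis first.
    piv = data.groupby([subject, *within], sort=False)[dv].mean()
    idx = pd.MultiIndex.from_product(
        [list(subjects)] + [levels[f] for f in within],
        names=[subject, *within])
    y = piv.reindex(idx).to_numpy().reshape(shape)
    if np.isnan(y).any():
        raise StatsError("missing cells in the design")

    factor_axis = {f: i + 1 for i, f in enumerate(within)}
    rows = []
    for r in range(1, len(within) + 1):
        for eff in itertools.combinations(within, r):
            other = [f for f in within if f not in eff]
            # Per-subject data collapsed over the non-effect factors.
            z = y.mean(axis=tuple(factor_axis[f] for f in other)) \
                if other else y
            z2 = z.reshape(n, -1)  # n × (cells of the effect)
            # Inclusion–exclusion effect estimate per subject and cell.
            g = np.zeros_like(z)
            eff_axes = tuple(range(1, r + 1))
            for k in range(r + 1):
                for sub in itertools.combinations(eff_axes, k):
                    keep = z.mean(axis=tuple(a for a in eff_axes
                                             if a not in sub), keepdims=True)
                    g = g + (-1) ** (r - k) * keep
            gbar = g.mean(axis=0, keepdims=True)
            scale = float(np.prod([len(levels[f]) for f in other])) if other else 1.0
            ss_eff = scale * n * float((gbar ** 2).sum())
            ss_err = scale * float(((g - gbar) ** 2).sum())
            df1 = int(np.prod([len(levels[f]) - 1 for f in eff]))
            df2 = df1 * (n - 1)
            ms_eff = ss_eff / df1
            ms_err = ss_err / df2 if df2 else np.nan
            f_val = ms_eff / ms_err if ms_err > 0 else 0.0
            p_unc = float(_sps.f.sf(f_val, df1, df2))
            # GG epsilon from the orthonormal contrast scores of this effect.
            c = np.ones((1, 1))
            for f in eff:
                c = np.kron(c, _orthonormal_contrasts(len(levels[f])))
            # Need z collapsed to the effect cells in a consistent order.
            scores = z2 @ c.T
            eps = _gg_epsilon(scores)
            p_gg = float(_sps.f.sf(f_val, df1 * eps, df2 * eps))
            rows.append({
                "effect": " * ".join(eff), "F": float(f_val),
                "df_num": df1, "df_den": df2,
                "ss_effect": ss_eff, "ss_error": ss_err, "ms_error": ms_err,
                "epsilon_gg": eps, "p_uncorrected": p_unc,
                "p_gg": p_gg if df1 > 1 or eps < 1 else p_unc,
                "partial_eta_sq": ss_eff / (ss_eff + ss_err)
                if (ss_eff + ss_err) > 0 else 0.0,
            })
    return pd.DataFrame(rows)


def fisher_lsd(cell_means: Mapping[str, float], ms_error: float, df_error: int,
               n_per_cell: int) -> pd.DataFrame:
    """Unadjusted pairwise comparisons of cell means using a fitted ANOVA's
    error mean square (least significant difference method)."""
    if len(cell_means) < 2:
        raise StatsError("need at least 2 cells for pairwise comparisons")
    if not np.isfinite(ms_error) or ms_error < 0 or df_error < 1:
        raise StatsError("invalid error term (is the ANOVA fitted?)")
    names = list(cell_means)
    rows = []
    se = np.sqrt(2.0 * ms_error / n_per_cell)
    for a, b in itertools.combinations(names, 2):
        diff = cell_means[a] - cell_means[b]
        t = diff / se if se > 0 else 0.0
        p = 2.0 * _sps.t.sf(abs(t), df_error)
        rows.append({"a": a, "b": b, "diff": diff, "t": float(t),
                     "df": df_error, "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phase-level analyses
# ---------------------------------------------------------------------------

@dataclass
class LearningResult:
    anova: pd.DataFrame  # condition x block x electrode
    block_means: pd.DataFrame  # all-channel mean per condition x block
    posthoc: pd.DataFrame  # LSD block contrast per condition


def learning_contrast(amplitudes: pd.DataFrame) -> LearningResult:
    """Learning-phase analysis: condition × block × electrode repeated-measures
    ANOVA on the 200–500 ms window means, plus the all-channel block contrast
    per condition (Fisher LSD on the condition×block cell means)."""
    df = amplitudes.rename(columns={"cell": "block"})
    if df["condition"].nunique() < 2:
        raise StatsError("learning contrast needs both conditions")
    anova = rm_anova(df, dv="amplitude_uv",
                     within=["condition", "block", "channel"])
    # All-channel means per subject x condition x block.
    cellwise = (df.groupby(["subject", "condition", "block"], sort=False)
                ["amplitude_uv"].mean().reset_index())
    summary = (cellwise.groupby(["condition", "block"], sort=False)
               ["amplitude_uv"].agg(["mean", "std"]).reset_index())
    small = rm_anova(cellwise, dv="amplitude_uv", within=["condition", "block"])
    err = small.loc[small["effect"] == "condition * block"].iloc[0]
    n = cellwise["subject"].nunique()
    posthocs = []
    for cond, grp in cellwise.groupby("condition", sort=False):
        means = grp.groupby("block", sort=False)["amplitude_uv"].mean()
        lsd = fisher_lsd(means.to_dict(), err["ms_error"],
                         int(err["df_den"]), n)
        lsd.insert(0, "condition", cond)
        posthocs.append(lsd)
    return LearningResult(anova=anova, block_means=summary,
                          posthoc=pd.concat(posthocs, ignore_index=True))


@dataclass
class TestPhaseResult:
    ttests: pd.DataFrame  # per condition x window x electrode, with FDR
    anovas: pd.DataFrame  # item_type x electrode per condition/window
    condition_anovas: pd.DataFrame  # condition x electrode on difference waves


def _difference_table(amplitudes: pd.DataFrame) -> pd.DataFrame:
    """Per-subject illegal − legal difference per condition/window/channel."""
    df = amplitudes.rename(columns={"cell": "item_type"})
    keys = ["subject", "condition", "win_lo_ms", "win_hi_ms", "channel"]
    wide = df.pivot_table(index=keys, columns="item_type",
                          values="amplitude_uv").reset_index()
    if "illegal" not in wide or "legal" not in wide:
        raise StatsError("need both legal and illegal cells")
    wide["difference"] = wide["illegal"] - wide["legal"]
    return wide


def test_phase_contrast(amplitudes: pd.DataFrame,
                        electrodes: Sequence[str] = TEST_T_ELECTRODES
                        ) -> TestPhaseResult:
    """Test-phase mismatch analysis.

    Per condition and window: (i) one-sample t of the illegal−legal difference
    against zero at each electrode of `electrodes`, BH-FDR-corrected within
    the electrode family; (ii) item-type × electrode ANOVA over all channels.
    Per window: condition × electrode ANOVA on the difference waveforms.
    """
    diffs = _difference_table(amplitudes)
    t_rows, anova_rows, cond_rows = [], [], []
    for (cond, lo, hi), grp in diffs.groupby(
            ["condition", "win_lo_ms", "win_hi_ms"], sort=False):
        fam = []
        for ch in electrodes:
            vals = grp.loc[grp["channel"] == ch, "difference"].to_numpy()
            res = one_sample_t(vals)
            fam.append({"condition": cond, "win_lo_ms": lo, "win_hi_ms": hi,
                        "channel": ch, "m": res.m, "sd": res.sd, "t": res.t,
                        "df": res.df, "p": res.p, "cohens_d": res.cohens_d})
        ps = fdr_bh([r["p"] for r in fam])
        for r, q in zip(fam, ps):
            r["p_fdr"] = float(q)
        t_rows.extend(fam)
    df = amplitudes.rename(columns={"cell": "item_type"})
    for (cond, lo, hi), grp in df.groupby(
            ["condition", "win_lo_ms", "win_hi_ms"], sort=False):
        a = rm_anova(grp, dv="amplitude_uv", within=["item_type", "channel"])
        a.insert(0, "condition", cond)
        a.insert(1, "win_lo_ms", lo)
        a.insert(2, "win_hi_ms", hi)
        anova_rows.append(a)
    for (lo, hi), grp in diffs.groupby(["win_lo_ms", "win_hi_ms"], sort=False):
        if grp["condition"].nunique() > 1:
            a = rm_anova(grp.rename(columns={"difference": "amplitude_uv"}),
                         dv="amplitude_uv", within=["condition", "channel"])
            a.insert(0, "win_lo_ms", lo)
            a.insert(1, "win_hi_ms", hi)
            cond_rows.append(a)
    return TestPhaseResult(
        ttests=pd.DataFrame(t_rows),
        anovas=pd.concat(anova_rows, ignore_index=True),
        condition_anovas=(pd.concat(cond_rows, ignore_index=True)
                          if cond_rows else pd.DataFrame()),
    )
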