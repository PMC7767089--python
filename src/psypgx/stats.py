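"""Before/after cohort statistics: paired tests, dose variation, power.

Two distinct "variation" conventions are implemented and labelled:

* ``percent_change`` / ratio-of-means — the change of a cohort-level total or
  mean, 100 x (after - before) / before;
* ``within_patient_variation`` — the mean over patients of each patient's own
  percent dose change, with SD and a t-based 95% CI. The excluding-switches
  variant keeps only patients prescribed the drug in both epochs; the
  including-switches variant keeps everyone on the drug before testing and
  scores discontinuation as -100%.

The paired tests are authored here because their exact small-sample modes are
part of the analysis contract: the Wilcoxon signed-rank test uses the exact
null distribution of the positive rank sum (tied mid-ranks handled by
convolution over doubled ranks) up to n = 25 and a continuity- and
tie-corrected normal approximation above; McNemar's test is an exact
binomial test for b + c < 25 discordant pairs and a continuity-corrected
chi-square otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PairedTestResult:
    test: str
    statistic: float
    p_value: float
    n_effective: int

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise StatsError(f"p-value out of range: {self.p_value}")


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100 x (after - before) / before."""
    if before == 0:
        raise StatsError("percent_change undefined for before == 0")
    return 100.0 * (after - before) / before


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding that matches hand-rounded tables (0.005 -> 0.01)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class VariationSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n: int


def within_patient_variation(changes: Sequence[float]) -> VariationSummary:
    """Mean, SD (ddof=1) and 95% t-CI of per-patient percent changes."""
    arr = np.asarray(changes, dtype=float)
    n = arr.size
    if n == 0:
        raise StatsError("no patients after filtering")
    mean = float(arr.mean())
    if n == 1:
        return VariationSummary(mean, 0.0, mean, mean, 1)
    sd = float(arr.std(ddof=1))
    half = sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return VariationSummary(mean, sd, mean - half, mean + half, n)


def paired_dose_changes(
    pre: dict[str, float], post: dict[str, float], include_switches: bool
) -> list[float]:
    """Per-patient percent dose changes from patient->dose maps of both epochs.

    ``include_switches=False`` keeps only patients dosed in both epochs;
    ``True`` keeps every patient dosed before testing, scoring
    discontinuation (absent or zero after) as -100%.
    """
    changes = []
    for pid, before in pre.items():
        if before <= 0:
            continue
        after = post.get(pid, 0.0)
        if include_switches:
            changes.append(percent_change(before, after))
        elif after > 0:
            changes.append(percent_change(before, after))
    return changes


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_wplus_distribution(double_ranks: Sequence[int]) -> np.ndarray:
    """Counts of each value of 2*W+ over all 2^n equiprobable sign vectors."""
    total = int(sum(double_ranks))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    alternative: str = "two-sided",
    exact_cutoff: int = 25,
) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired samples (or precomputed differences).

    Zero differences are dropped (and excluded from ``n_effective``); ties
    among the remaining absolute differences receive mid-ranks. Exact null
    distribution for n_effective <= ``exact_cutoff``, normal approximation
    with continuity and tie correction above. Statistic is W+ (sum of ranks
    of positive differences).
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise StatsError(f"bad alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return PairedTestResult("wilcoxon_signed_rank", 0.0, 1.0, 0)

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_cutoff:
        double_ranks = np.rint(2 * ranks).astype(int)
        counts = _exact_wplus_distribution(double_ranks)
        total = counts.sum()  # 2^n
        w2 = int(round(2 * w_plus))
        cdf = counts[: w2 + 1].sum() / total
        sf = counts[w2:].sum() / total
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(cdf, sf))
        return PairedTestResult("wilcoxon_signed_rank", w_plus, float(p), n)

    mean = n * (n + 1) / 4.0
    # tie correction on the variance of W+
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / sd
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (w_plus - mean + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        z = (w_plus - mean - math.copysign(0.5, w_plus - mean)) / sd
        p = 2 * sps.norm.sf(abs(z))
    return PairedTestResult("wilcoxon_signed_rank", w_plus, float(min(1.0, p)), n)


# ---------------------------------------------------------------------------
# McNemar


def mcnemar(b: int, c: int, exact_cutoff: int = 25) -> PairedTestResult:
    """McNemar's test from discordant pair counts (b: yes->no, c: no->yes).

    Exact two-sided binomial test when b + c < ``exact_cutoff``; chi-square
    with continuity correction otherwise.
    """
    if b < 0 or c < 0:
        raise StatsError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return PairedTestResult("mcnemar", 0.0, 1.0, 0)
    if n < exact_cutoff:
        k = min(b, c)
        p = min(1.0, 2.0 * float(sps.binom.cdf(k, n, 0.5)))
        return PairedTestResult("mcnemar", float(k), p, n)
    stat = (abs(b - c) - 1) ** 2 / n
    p = float(sps.chi2.sf(stat, df=1))
    return PairedTestResult("mcnemar", float(stat), p, n)


# ---------------------------------------------------------------------------
# power


def paired_power(
    mean_delta: float,
    sd: float,
    n: int,
    alpha: float = 0.05,
    alternative: str = "one-sided",
) -> float:
    """Power of a paired t-test for a mean within-pair difference.

    ``mean_delta`` and ``sd`` are the mean and SD of the paired differences
    (mg/d in the dosing application); the noncentral t distribution with
    n - 1 degrees of freedom gives the power.
    """
    if not 0 < alpha < 1:
        raise StatsError(f"alpha out of range: {alpha}")
    if sd <= 0:
        raise StatsError("sd must be > 0")
    if n < 2:
        raise StatsError("n must be >= 2")
    df = n - 1
    ncp = mean_delta / (sd / math.sqrt(n))
    if alternative == "one-sided":
        tcrit = sps.t.ppf(1 - alpha, df)
        return float(sps.nct.sf(tcrit, df, ncp))
    if alternative == "two-sided":
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
    raise StatsError(f"bad alternative {alternative!r}")


# ---------------------------------------------------------------------------
# cohort summary


def per_drug_table(rx_df: pd.DataFrame) -> pd.DataFrame:
    """Prescription counts and mean/min/max daily dose per (drug, route, epoch)."""
    if rx_df.empty:
        return pd.DataFrame(
            columns=["drug", "route", "epoch", "n", "mean_dose", "min_dose", "max_dose"]
        )
    g = (
        rx_df.groupby(["drug", "route", "epoch"], sort=True)["daily_dose"]
        .agg(n="size", mean_dose="mean", min_dose="min", max_dose="max")
        .reset_index()
    )
    return g


def cohort_summary(
    patients_df: pd.DataFrame,
    rx_df: pd.DataFrame,
    kb,
) -> dict:
    """Aggregate before/after summary of a cohort (counts, doses, tests).

    Returns a JSON-serialisable dict with per-epoch totals, polypharmacy
    rates, the per-drug table, within-patient dose variation (both switch
    conventions), chlorpromazine dose bins, and the paired tests on the
    chlorpromazine total and on the polypharmacy indicators.
    """
    from .dosing import dose_bins, summarize_patient
    from .records import records_from_frames

    patients = records_from_frames(patients_df, rx_df)
    n_patients = len(patients)
    if n_patients == 0:
        raise StatsError("empty cohort")

    epochs = sorted(rx_df["epoch"].unique()) if not rx_df.empty else []
    out: dict = {"n_patients": n_patients, "epochs": {}}

    cpz_by_epoch: dict[str, dict[str, float]] = {}
    summaries = []
    for epoch in epochs:
        sub = rx_df[rx_df["epoch"] == epoch]
        is_ap = sub["drug"].map(lambda d: kb.profile(d).antipsychotic)
        n_drugs_pp = sub.groupby("patient_id").size()
        n_ap_pp = sub[is_ap].groupby("patient_id")["drug"].nunique()
        cpz = {}
        for p in patients:
            rx = p.prescriptions_for(epoch)
            if rx:
                s = summarize_patient(rx, kb)
                summaries.append(s)
                cpz[p.patient_id] = s.cpz_total
        cpz_by_epoch[epoch] = cpz
        out["epochs"][epoch] = {
            "n_drugs": int(len(sub)),
            "n_antipsychotics": int(is_ap.sum()),
            "avg_drugs_per_patient": float(len(sub) / n_patients),
            "avg_antipsychotics_per_patient": float(is_ap.sum() / n_patients),
            "pct_gt5_drugs": float(100.0 * (n_drugs_pp > 5).sum() / n_patients),
            "pct_gt1_antipsychotic": float(100.0 * (n_ap_pp > 1).sum() / n_patients),
            "mean_cpz": float(np.mean(list(cpz.values()))) if cpz else 0.0,
            "dose_bins": dose_bins(summaries, epoch) if cpz else None,
        }

    out["per_drug"] = per_drug_table(rx_df).to_dict(orient="records")

    if set(epochs) >= {"pre", "post"}:
        pre, post = cpz_by_epoch["pre"], cpz_by_epoch["post"]
        paired_ids = sorted(set(pre) & set(post))
        pre_v = [pre[i] for i in paired_ids]
        post_v = [post[i] for i in paired_ids]

        out["percent_change"] = {
            "antipsychotic_prescriptions": percent_change(
                out["epochs"]["pre"]["n_antipsychotics"],
                out["epochs"]["post"]["n_antipsychotics"],
            ),
            "mean_cpz": percent_change(
                out["epochs"]["pre"]["mean_cpz"], out["epochs"]["post"]["mean_cpz"]
            ),
        }
        cpz_changes = paired_dose_changes(pre, post, include_switches=True)
        v = within_patient_variation(cpz_changes)
        out["within_patient_cpz_variation"] = {
            "mean": v.mean, "sd": v.sd, "ci95": [v.ci_low, v.ci_high], "n": v.n,
        }

        out["within_patient_drug_variation"] = {}
        ap_rx = rx_df[rx_df["drug"].map(lambda d: kb.profile(d).antipsychotic)]
        for drug in sorted(ap_rx["drug"].unique()):
            per_epoch = {}
            for epoch in ("pre", "post"):
                sub = ap_rx[(ap_rx["drug"] == drug) & (ap_rx["epoch"] == epoch)]
                per_epoch[epoch] = sub.groupby("patient_id")["daily_dose"].sum().to_dict()
            entry = {}
            for label, include in (("excluding_switches", False), ("including_switches", True)):
                changes = paired_dose_changes(per_epoch["pre"], per_epoch["post"], include)
                if changes:
                    v = within_patient_variation(changes)
                    entry[label] = {
                        "mean": v.mean, "sd": v.sd,
                        "ci95": [v.ci_low, v.ci_high], "n": v.n,
                    }
            if entry:
                out["within_patient_drug_variation"][drug] = entry

        wil = wilcoxon_signed_rank(post_v, pre_v, alternative="two-sided")
        out["tests"] = {
            "cpz_wilcoxon": {
                "statistic": wil.statistic, "p_value": wil.p_value, "n": wil.n_effective,
            }
        }
        for name, col in (
            ("polypharmacy_mcnemar", "pct_gt1_antipsychotic"),
            ("gt5_drugs_mcnemar", "pct_gt5_drugs"),
        ):
            flag = {}
            for epoch in ("pre", "post"):
                sub = rx_df[rx_df["epoch"] == epoch]
                if col == "pct_gt1_antipsychotic":
                    is_ap = sub["drug"].map(lambda d: kb.profile(d).antipsychotic)
                    counts = sub[is_ap].groupby("patient_id")["drug"].nunique()
                    flag[epoch] = {pid: n > 1 for pid, n in counts.items()}
                else:
                    counts = sub.groupby("patient_id").size()
                    flag[epoch] = {pid: n > 5 for pid, n in counts.items()}
            ids = sorted(set(flag["pre"]) | set(flag["post"]))
            b = sum(
                1 for i in ids if flag["pre"].get(i, False) and not flag["post"].get(i, False)
            )
            c = sum(
                1 for i in ids if not flag["pre"].get(i, False) and flag["post"].get(i, False)
            )
            res = mcnemar(b, c)
            out["tests"][name] = {
                "b": b, "c": c, "statistic": res.statistic, "p_value": res.p_value,
            }
        out["note"] = (
            "p-values are reported without multiplicity correction across the "
            "paired tests"
        )
    return out
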