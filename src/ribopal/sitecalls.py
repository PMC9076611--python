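"""Differential MaP site calling from PAL/PRE/UV/NUL count tables.

Mutation rates are M/C per condition (replicates pooled by summing counts).
Candidate photolabeled sites must pass a four-part screen: fold change
PAL/PRE >= 1.5, average PAL/PRE mutation count >= 100, Z-factor > 0 and
p < 0.05. The Z-factor compares the normalized rates N = M/A of the two
samples against their binomial sampling noise:

    z = 1 - 1.96 * (sigma_PAL + sigma_PRE) / |N_PAL - N_PRE|,
    sigma_X = sqrt(rate_X / C_X) / A,   A = (rate_PAL + rate_PRE) / 2.

UV-crosslink artifacts and native modifications are flagged from the
UV/NUL contrast and the NUL rate respectively, and take precedence over
the candidate category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ribopal.synth import CONDITIONS

__all__ = [
    "CallThresholds",
    "ZFactorResult",
    "call_candidate_sites",
    "call_sites",
    "classify_native_mods",
    "classify_uv_sites",
    "compute_profiles",
    "correct_pi_stoppost5",
    "fold_change",
    "fragment_stoichiometry",
    "load_counts",
    "site_pvalue",
    "write_bed",
    "zfactor",
]

_COUNT_COLUMNS = ["transcript", "position", "ref_base", "condition", "replicate", "reads", "mutations"]


@dataclass(frozen=True)
class CallThresholds:
    """Screen thresholds; defaults follow the published filter cascade."""

    min_fold_change: float = 1.5
    min_avg_mut_count: float = 100.0
    min_z: float = 0.0
    max_p: float = 0.05
    coverage_floor: int = 100  # reads per condition below which a site is excluded
    uv_min_ratio: float = 10.0
    uv_min_delta: float = 0.01
    uv_min_avg_count: float = 100.0
    native_min_rate: float = 0.2
    a_mode: str = "per_site"  # normalization A: "per_site" or "per_transcript"


def load_counts(path) -> pd.DataFrame:
    """Read a counts TSV and validate every record.

    Expected columns: transcript, position, ref_base, condition, replicate,
    reads, mutations. Raises ValueError naming the offending line for
    malformed rows or mutation counts exceeding read depth.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts file {path} missing columns: {missing}")
    for col in ("position", "replicate", "reads", "mutations"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(coerced.index[coerced.isna()][0]) + 2  # header + 1-based
            raise ValueError(f"malformed value in column '{col}' at line {line} of {path}")
        df[col] = coerced.astype(np.int64)
    bad = df["mutations"] > df["reads"]
    if bad.any():
        row = df.loc[bad.idxmax()]
        raise ValueError(
            f"mutations > reads at {row['transcript']} position {row['position']} "
            f"(condition {row['condition']}, line {int(bad.idxmax()) + 2})"
        )
    if (df["position"] < 1).any():
        raise ValueError("positions must be >= 1")
    unknown = set(df["condition"].unique()) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions: {sorted(unknown)}")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def compute_profiles(records: pd.DataFrame, coverage_floor: int = 100) -> pd.DataFrame:
    """Pool replicates and compute per-position, per-condition mutation rates.

    Counts are summed across replicates before division (count pooling, not
    rate averaging). Positions whose pooled depth falls below
    ``coverage_floor`` in any present condition are flagged excluded; a zero
    depth yields rate NaN, never a division error.
    """
    pooled = (
        records.groupby(["transcript", "position", "condition"], sort=True)[["reads", "mutations"]]
        .sum()
        .reset_index()
    )
    wide = pooled.pivot(index=["transcript", "position"], columns="condition", values=["reads", "mutations"])
    profiles = pd.DataFrame(index=wide.index)
    present = [c for c in CONDITIONS if ("reads", c) in wide.columns]
    for cond in present:
        reads = wide[("reads", cond)].fillna(0).astype(np.int64)
        muts = wide[("mutations", cond)].fillna(0).astype(np.int64)
        profiles[f"reads_{cond}"] = reads
        profiles[f"mutations_{cond}"] = muts
        with np.errstate(invalid="ignore", divide="ignore"):
            profiles[f"rate_{cond}"] = np.where(reads > 0, muts / reads, np.nan)
    profiles["excluded"] = False
    for cond in present:
        profiles["excluded"] |= profiles[f"reads_{cond}"] < coverage_floor
    return profiles.reset_index()


class ZFactorResult(NamedTuple):
    A: np.ndarray
    sigma_pal: np.ndarray
    sigma_pre: np.ndarray
    delta_n: np.ndarray
    z: np.ndarray


def zfactor(rate_pal, c_pal, rate_pre, c_pre, A=None) -> ZFactorResult:
    """Z-factor separation statistic for a PAL/PRE rate pair.

    ``A`` defaults to the per-site mean of the two rates; pass a
    transcript-wide average to switch normalization conventions. A zero
    rate difference yields z = -inf (the site can never pass z > 0).
    Vectorized over array inputs.
    """
    rate_pal = np.asarray(rate_pal, dtype=float)
    rate_pre = np.asarray(rate_pre, dtype=float)
    c_pal = np.asarray(c_pal, dtype=float)
    c_pre = np.asarray(c_pre, dtype=float)
    if A is None:
        A = (rate_pal + rate_pre) / 2.0
    A = np.asarray(A, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_pal = np.sqrt(rate_pal / c_pal) / A
        sigma_pre = np.sqrt(rate_pre / c_pre) / A
        delta_n = (rate_pal - rate_pre) / A
        z = np.where(
            delta_n == 0,
            -np.inf,
            1.0 - 1.96 * (sigma_pal + sigma_pre) / np.abs(delta_n),
        )
    if np.ndim(z) == 0:
        return ZFactorResult(float(A), float(sigma_pal), float(sigma_pre), float(delta_n), float(z))
    return ZFactorResult(A, sigma_pal, sigma_pre, delta_n, z)


def site_pvalue(m_pal, c_pal, m_pre, c_pre) -> np.ndarray | float:
    """Two-sided p-value for equality of the two mutation proportions.

    Pooled two-proportion z-test; an exact conditional binomial test
    (M_PAL out of M_PAL + M_PRE against p = C_PAL/(C_PAL + C_PRE)) replaces
    it wherever any expected mutation cell is below 5. Vectorized.
    """
    m1 = np.atleast_1d(np.asarray(m_pal, dtype=float))
    m2 = np.atleast_1d(np.asarray(m_pre, dtype=float))
    c1 = np.atleast_1d(np.asarray(c_pal, dtype=float))
    c2 = np.atleast_1d(np.asarray(c_pre, dtype=float))
    pooled = (m1 + m2) / (c1 + c2)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(pooled * (1 - pooled) * (1 / c1 + 1 / c2))
        zstat = np.where(se > 0, (m1 / c1 - m2 / c2) / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(zstat))
    exact = (pooled * c1 < 5) | (pooled * c2 < 5)
    for i in np.flatnonzero(exact):
        total = int(m1[i] + m2[i])
        if total == 0:
            p[i] = 1.0
        else:
            p[i] = stats.binomtest(int(m1[i]), total, c1[i] / (c1[i] + c2[i])).pvalue
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if np.ndim(m_pal) == 0 else p


def fold_change(m_pal, c_pal, m_pre, c_pre) -> np.ndarray | float:
    """PAL/PRE mutation-rate ratio with a 0.5 pseudocount when PRE has
    zero mutations (keeps the ratio finite while preserving ranking)."""
    m1 = np.atleast_1d(np.asarray(m_pal, dtype=float))
    m2 = np.atleast_1d(np.asarray(m_pre, dtype=float))
    c1 = np.atleast_1d(np.asarray(c_pal, dtype=float))
    c2 = np.atleast_1d(np.asarray(c_pre, dtype=float))
    zero_pre = m2 == 0
    num = np.where(zero_pre, m1 + 0.5, m1)
    den = np.where(zero_pre, m2 + 0.5, m2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = (num / c1) / (den / c2)
    return float(fc[0]) if np.ndim(m_pal) == 0 else fc


def _sitecall_stats(profiles: pd.DataFrame, thresholds: CallThresholds) -> pd.DataFrame:
    out = profiles.copy()
    if thresholds.a_mode == "per_transcript":
        A = np.full(len(out), (out["rate_PAL"].mean() + out["rate_PRE"].mean()) / 2.0)
    elif thresholds.a_mode == "per_site":
        A = None
    else:
        raise ValueError(f"unknown a_mode {thresholds.a_mode!r}")
    zr = zfactor(out["rate_PAL"], out["reads_PAL"], out["rate_PRE"], out["reads_PRE"], A=A)
    out["A"] = zr.A
    out["sigma_PAL"] = zr.sigma_pal
    out["sigma_PRE"] = zr.sigma_pre
    out["delta_N"] = zr.delta_n
    out["z"] = zr.z
    out["fold_change"] = fold_change(
        out["mutations_PAL"], out["reads_PAL"], out["mutations_PRE"], out["reads_PRE"]
    )
    out["avg_mut_count"] = (out["mutations_PAL"] + out["mutations_PRE"]) / 2.0
    out["p_value"] = np.nan
    usable = ~out["excluded"]
    out.loc[usable, "p_value"] = site_pvalue(
        out.loc[usable, "mutations_PAL"].to_numpy(),
        out.loc[usable, "reads_PAL"].to_numpy(),
        out.loc[usable, "mutations_PRE"].to_numpy(),
        out.loc[usable, "reads_PRE"].to_numpy(),
    )
    return out


def call_candidate_sites(profiles: pd.DataFrame, thresholds: CallThresholds | None = None) -> pd.DataFrame:
    """Apply the four-part candidate screen to computed profiles.

    A position is a candidate iff fold change >= min_fold_change, average
    PAL/PRE mutation count >= min_avg_mut_count, z > min_z and
    p < max_p (and it is not excluded for coverage).
    """
    thresholds = thresholds or CallThresholds()
    stats_df = _sitecall_stats(profiles, thresholds)
    stats_df["candidate"] = (
        ~stats_df["excluded"]
        & (stats_df["fold_change"] >= thresholds.min_fold_change)
        & (stats_df["avg_mut_count"] >= thresholds.min_avg_mut_count)
        & (stats_df["z"] > thresholds.min_z)
        & (stats_df["p_value"] < thresholds.max_p)
    )
    return stats_df


def classify_uv_sites(profiles: pd.DataFrame, thresholds: CallThresholds | None = None) -> pd.Series:
    """Flag UV-crosslink artifacts from the UV/NUL contrast.

    Requires UV/NUL rate ratio > 10, UV - NUL rate difference > 0.01 and
    average UV/NUL mutation count > 100 (0.5 pseudocount when NUL has no
    mutations).
    """
    thresholds = thresholds or CallThresholds()
    for cond in ("UV", "NUL"):
        if f"rate_{cond}" not in profiles.columns:
            raise ValueError(f"condition {cond} missing from profiles")
    ratio = fold_change(
        profiles["mutations_UV"], profiles["reads_UV"], profiles["mutations_NUL"], profiles["reads_NUL"]
    )
    delta = profiles["rate_UV"] - profiles["rate_NUL"]
    avg_count = (profiles["mutations_UV"] + profiles["mutations_NUL"]) / 2.0
    return pd.Series(
        ~profiles["excluded"]
        & (ratio > thresholds.uv_min_ratio)
        & (delta > thresholds.uv_min_delta)
        & (avg_count > thresholds.uv_min_avg_count),
        index=profiles.index,
        name="uv_artifact",
    )


def classify_native_mods(profiles: pd.DataFrame, thresholds: CallThresholds | None = None) -> pd.Series:
    """Flag native modifications: NUL mutation rate >= 0.2."""
    thresholds = thresholds or CallThresholds()
    if "rate_NUL" not in profiles.columns:
        raise ValueError("condition NUL missing from profiles")
    return pd.Series(
        ~profiles["excluded"] & (profiles["rate_NUL"] >= thresholds.native_min_rate),
        index=profiles.index,
        name="native_mod",
    )


def call_sites(
    records: pd.DataFrame,
    thresholds: CallThresholds | None = None,
) -> pd.DataFrame:
    """Full pipeline: profiles -> statistics -> mutually exclusive categories.

    Category precedence: excluded > native_mod > uv_artifact > candidate >
    background.
    """
    thresholds = thresholds or CallThresholds()
    profiles = compute_profiles(records, coverage_floor=thresholds.coverage_floor)
    calls = call_candidate_sites(profiles, thresholds)
    have_uvnul = {"rate_UV", "rate_NUL"} <= set(calls.columns)
    native = classify_native_mods(calls, thresholds) if "rate_NUL" in calls.columns else pd.Series(False, index=calls.index)
    uv = classify_uv_sites(calls, thresholds) if have_uvnul else pd.Series(False, index=calls.index)

    category = np.full(len(calls), "background", dtype=object)
    category[calls["candidate"].to_numpy()] = "candidate"
    category[uv.to_numpy()] = "uv_artifact"
    category[native.to_numpy()] = "native_mod"
    category[calls["excluded"].to_numpy()] = "excluded"
    calls["category"] = category
    return calls


def write_bed(calls: pd.DataFrame, path) -> None:
    """BED-like export: transcript, start0, end0, category, z."""
    bed = pd.DataFrame(
        {
            "transcript": calls["transcript"],
            "start0": calls["position"] - 1,
            "end0": calls["position"],
            "category": calls["category"],
            "z": calls["z"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def correct_pi_stoppost5(pi_measured: float, pi_ires: float, f: float = 0.40) -> float:
    """Occupancy-correct a measured labeling stoichiometry.

    A Stop-POST5 preparation carries peptidyl-tRNA on only a fraction ``f``
    of ribosomes (0.40 +/- 0.05 here); the remainder is 80S.IRES. The
    corrected per-pretermination-complex stoichiometry is
    ``(1/f) * (pi_measured - (1 - f) * pi_ires)``; with f = 0.40 this is
    the familiar 2.5 * (measured - 0.6 * ires). Negative corrected values
    are allowed but warned about.
    """
    if not 0 < f <= 1:
        raise ValueError("occupancy f must lie in (0, 1]")
    corrected = (1.0 / f) * (pi_measured - (1.0 - f) * pi_ires)
    if corrected < 0:
        warnings.warn("occupancy-corrected stoichiometry is negative", stacklevel=2)
    return corrected


def fragment_stoichiometry(raw_mole_percent: float, recovery: float = 0.20) -> float:
    """Correct an RNase-H fragment labeling yield for gel recovery
    (default recovery 20%)."""
    if recovery <= 0:
        raise ValueError("recovery must be > 0")
    return raw_mole_percent / recovery
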