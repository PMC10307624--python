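"""Phosphosite-group quantification and differential statistics.

Peptides carrying the same set of phosphorylated sites on the same protein
are grouped and quantified together (summed on the linear scale within a
run); runs are equal-median normalized on the log2 scale; each stimulation
condition is contrasted against its time-matched control with a two-sided
Welch t test; p values get Benjamini-Hochberg correction per contrast; and
per-site fold changes are collapsed by the lowest-p rule, discarding
infinite log2 fold changes.
"""

from __future__ import annotations

import logging
import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import PHOSPHO_RESIDUES

logger = logging.getLogger(__name__)

_SITE_RE = re.compile(r"^([STY])(\d+)$")

#: variance floor used when a t test meets a zero-variance group
VARIANCE_FLOOR = 1e-8


def parse_sites(site_str: str) -> tuple[tuple[int, str], ...]:
    """Parse ``"S15;T20"`` into ``((15, "S"), (20, "T"))``, validated.

    Positions must be 1-based, strictly increasing; residues S/T/Y only.
    """
    if not isinstance(site_str, str) or not site_str:
        raise ValueError(f"malformed site string: {site_str!r}")
    out = []
    for token in site_str.split(";"):
        m = _SITE_RE.match(token.strip())
        if not m:
            raise ValueError(f"malformed site token {token!r} in {site_str!r}")
        out.append((int(m.group(2)), m.group(1)))
    positions = [p for p, _ in out]
    if positions != sorted(positions) or len(set(positions)) != len(positions):
        raise ValueError(f"site positions must be strictly increasing: {site_str!r}")
    if any(p < 1 for p in positions):
        raise ValueError(f"site positions must be 1-based: {site_str!r}")
    return tuple(out)


def site_group_key(protein: str, sites: tuple[tuple[int, str], ...]) -> str:
    """Canonical site-group key, e.g. ``"PROT1_S15_T20"``.

    Underscores in accessions would break key parsing, so they are rejected.
    """
    if "_" in protein:
        raise ValueError(f"protein accession may not contain '_': {protein!r}")
    return "_".join([protein] + [f"{res}{pos}" for pos, res in sites])


def build_site_groups(
    measurements: pd.DataFrame,
    sequences: dict[str, str] | None = None,
    linear_scale: bool = False,
) -> pd.DataFrame:
    """Aggregate peptide measurements into phosphorylation site groups.

    Peptides with an identical (protein, phosphosite-set) are one group;
    within each run their intensities are summed on the linear scale and
    re-logged. Returns one row per (site group, run) with columns
    ``site_key, protein, site_positions, run, condition, timepoint,
    replicate, intensity`` (log2).

    When ``sequences`` is given, every position is checked against the
    protein length and residue identity. ``linear_scale`` declares that the
    input intensity column is linear rather than log2.
    """
    if measurements.empty:
        return pd.DataFrame(
            columns=[
                "site_key",
                "protein",
                "site_positions",
                "run",
                "condition",
                "timepoint",
                "replicate",
                "intensity",
            ]
        )
    df = measurements.copy()
    parsed = {s: parse_sites(s) for s in df["site_positions"].unique()}
    if sequences is not None:
        for (prot, s) in set(zip(df["protein"], df["site_positions"])):
            seq = sequences.get(prot)
            if seq is None:
                raise KeyError(f"protein {prot} missing from sequence set")
            for pos, res in parsed[s]:
                if pos > len(seq):
                    raise ValueError(
                        f"site {res}{pos} beyond length {len(seq)} of {prot}"
                    )
    df["site_key"] = [
        site_group_key(p, parsed[s]) for p, s in zip(df["protein"], df["site_positions"])
    ]
    intensity = df["intensity"].astype(float)
    linear = intensity if linear_scale else np.exp2(intensity)
    if not np.isfinite(linear).all():
        raise ValueError("intensities must be finite")
    df = df.assign(_linear=linear)
    grouped = (
        df.groupby(
            ["site_key", "protein", "site_positions", "run", "condition", "timepoint", "replicate"],
            as_index=False,
        )["_linear"]
        .sum()
        .rename(columns={"_linear": "intensity"})
    )
    grouped["intensity"] = np.log2(grouped["intensity"])
    return grouped


def to_matrix(grouped: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot grouped measurements into a (site group x run) log2 matrix.

    Returns the matrix (NaN for unobserved cells) and a run-metadata frame
    indexed by run with condition/timepoint/replicate columns.
    """
    matrix = grouped.pivot_table(
        index="site_key", columns="run", values="intensity", aggfunc="first"
    ).sort_index()
    meta = (
        grouped[["run", "condition", "timepoint", "replicate"]]
        .drop_duplicates()
        .set_index("run")
        .sort_index()
    )
    matrix = matrix[meta.index]
    return matrix, meta


def equal_median_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Shift each run (column) so all run medians equal the grand median.

    The grand median is the median of pre-normalization run medians; shifts
    are additive on the log2 scale, so fold changes are unaffected by any
    common constant. Raises if a run has no finite values.
    """
    medians = matrix.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ValueError(f"runs with no finite values: {bad}")
    target = float(np.median(medians.to_numpy()))
    return matrix - (medians - target)


def bh_adjust(pvalues: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("p values must be NaN-free (filter undefined entries first)")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch(
    treated: np.ndarray, control: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t test on two NaN-bearing matrices.

    Returns (log2FC, se, p, n_treated, n_control); p is NaN where either
    side has fewer than two finite values. Zero-variance rows use a
    variance floor, except exactly-equal means which get p = 1.
    """
    nt = np.sum(np.isfinite(treated), axis=1)
    nc = np.sum(np.isfinite(control), axis=1)
    # empty/singleton slices yield NaN by design; silence numpy's warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mt = np.nanmean(np.where(np.isfinite(treated), treated, np.nan), axis=1)
        mc = np.nanmean(np.where(np.isfinite(control), control, np.nan), axis=1)
        vt = np.nanvar(np.where(np.isfinite(treated), treated, np.nan), axis=1, ddof=1)
        vc = np.nanvar(np.where(np.isfinite(control), control, np.nan), axis=1, ddof=1)

    fc = np.full(treated.shape[0], np.nan)
    both = (nt > 0) & (nc > 0)
    fc[both] = mt[both] - mc[both]
    fc[(nt > 0) & (nc == 0)] = np.inf
    fc[(nt == 0) & (nc > 0)] = -np.inf

    testable = (nt >= 2) & (nc >= 2)
    vt_f = np.maximum(vt, VARIANCE_FLOOR)
    vc_f = np.maximum(vc, VARIANCE_FLOOR)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(vt_f / nt + vc_f / nc)
        t = fc / se
        df = (vt_f / nt + vc_f / nc) ** 2 / (
            (vt_f / nt) ** 2 / (nt - 1) + (vc_f / nc) ** 2 / (nc - 1)
        )
    p = np.full(treated.shape[0], np.nan)
    p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), df[testable])
    degenerate = testable & (vt < VARIANCE_FLOOR) & (vc < VARIANCE_FLOOR) & (fc == 0)
    p[degenerate] = 1.0
    se[~both] = np.nan
    return fc, se, p, nt, nc


def differential_test(
    matrix: pd.DataFrame,
    run_meta: pd.DataFrame,
    condition: str,
    timepoint: str,
    control: str = "US",
) -> pd.DataFrame:
    """Contrast one (condition, timepoint) against its time-matched control.

    Returns a SiteStat table: ``site_key, condition, timepoint, log2fc, se,
    p, adj_p, n_treated, n_control``. log2FC is the difference of log2
    means; sites observed on one side only get an infinite log2FC and an
    undefined p; BH adjustment is applied within this contrast over the
    defined p values. Both sides need >= 2 replicates somewhere in the
    design, else the contrast is rejected.
    """
    t_runs = run_meta.index[
        (run_meta["condition"] == condition) & (run_meta["timepoint"].astype(str) == str(timepoint))
    ]
    c_runs = run_meta.index[
        (run_meta["condition"] == control) & (run_meta["timepoint"].astype(str) == str(timepoint))
    ]
    if len(t_runs) == 0 or len(c_runs) == 0:
        raise ValueError(
            f"unknown contrast: {condition}/{timepoint} vs {control}/{timepoint}"
        )
    if len(t_runs) < 2 or len(c_runs) < 2:
        raise ValueError("need >= 2 replicate runs on each side of the contrast")

    fc, se, p, nt, nc = _welch(
        matrix[t_runs].to_numpy(float), matrix[c_runs].to_numpy(float)
    )
    out = pd.DataFrame(
        {
            "site_key": matrix.index,
            "condition": condition,
            "timepoint": str(timepoint),
            "log2fc": fc,
            "se": se,
            "p": p,
            "n_treated": nt,
            "n_control": nc,
        }
    )
    out = out[(out["n_treated"] > 0) | (out["n_control"] > 0)].reset_index(drop=True)
    adj = np.full(len(out), np.nan)
    defined = out["p"].notna().to_numpy()
    if defined.any():
        adj[defined] = bh_adjust(out.loc[defined, "p"].to_numpy())
    out["adj_p"] = adj
    return out


def run_contrasts(
    matrix: pd.DataFrame,
    run_meta: pd.DataFrame,
    ligands: list[str] | None = None,
    timepoints: list[str] | None = None,
    control: str = "US",
) -> pd.DataFrame:
    """Differential tests for every (ligand, timepoint) vs time-matched control."""
    if ligands is None:
        ligands = sorted(set(run_meta["condition"]) - {control})
    if timepoints is None:
        timepoints = sorted(run_meta["timepoint"].astype(str).unique())
    tables = [
        differential_test(matrix, run_meta, lig, tp, control=control)
        for lig in ligands
        for tp in timepoints
    ]
    return pd.concat(tables, ignore_index=True)


def _explode_sites(stats_df: pd.DataFrame) -> pd.DataFrame:
    df = stats_df.copy()
    tokens = df["site_key"].str.split("_")
    df["protein"] = tokens.str[0]
    df["_site"] = tokens.str[1:]
    df = df.explode("_site", ignore_index=True)
    df["position"] = df["_site"].str[1:].astype(int)
    df["residue"] = df["_site"].str[0]
    return df.drop(columns="_site")


def collapse_site_fc(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Reduce per-site-group statistics to a single fold change per site.

    Each site group contributes its (FC, p) to every member site; per
    (protein, position, contrast) the record with the lowest p among
    noninfinite log2FCs wins, ties broken by larger \\|FC\\| then by
    site-group key. Sites whose records are all infinite are omitted with
    a logged notice.
    """
    cols = [
        "protein",
        "position",
        "residue",
        "condition",
        "timepoint",
        "fc",
        "source_p",
        "adj_p",
        "site_key",
    ]
    if stats_df.empty:
        return pd.DataFrame(columns=cols)
    per_site = _explode_sites(stats_df)
    finite = per_site[np.isfinite(per_site["log2fc"])].copy()
    n_dropped_sites = (
        per_site.groupby(["protein", "position", "condition", "timepoint"]).size().shape[0]
        - finite.groupby(["protein", "position", "condition", "timepoint"]).size().shape[0]
    )
    if n_dropped_sites:
        logger.info(
            "collapse_site_fc: %d site/contrast entries had only infinite FCs and were omitted",
            n_dropped_sites,
        )
    if finite.empty:
        return pd.DataFrame(columns=cols)
    finite["_p_order"] = finite["p"].fillna(np.inf)
    finite["_abs_fc"] = finite["log2fc"].abs()
    finite = finite.sort_values(
        ["protein", "position", "condition", "timepoint", "_p_order", "_abs_fc", "site_key"],
        ascending=[True, True, True, True, True, False, True],
    )
    best = finite.drop_duplicates(
        subset=["protein", "position", "condition", "timepoint"], keep="first"
    )
    out = best.rename(columns={"log2fc": "fc", "p": "source_p"})[cols]
    return out.reset_index(drop=True)


def select_changed_proteins(
    stats_df: pd.DataFrame, fdr: float = 0.05, ligand: str | None = None
) -> set[str]:
    """Proteins with >= 1 site at adjusted p < ``fdr`` in >= 1 timepoint.

    ``ligand`` restricts to one stimulation condition; the default pools
    all conditions present.
    """
    df = stats_df
    if ligand is not None:
        df = df[df["condition"] == ligand]
    hits = df[df["adj_p"].notna() & (df["adj_p"] < fdr)]
    return set(hits["site_key"].str.split("_").str[0])


def quantify(
    measurements: pd.DataFrame,
    sequences: dict[str, str] | None = None,
    control: str = "US",
    linear_scale: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full quant stage: group, normalize, test all contrasts, collapse.

    Returns (site_stats, site_fc).
    """
    grouped = build_site_groups(measurements, sequences, linear_scale=linear_scale)
    matrix, meta = to_matrix(grouped)
    matrix = equal_median_normalize(matrix)
    site_stats = run_contrasts(matrix, meta, control=control)
    site_fc = collapse_site_fc(site_stats)
    return site_stats, site_fc
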