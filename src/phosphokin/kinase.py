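"""Kinase-activity inference from substrate fold changes (KSEA-style).

For each kinase with at least two measured substrate phosphosites in a
contrast, activity is the z statistic

    z = (M - u) / se,    se = sd / sqrt(m)

where M is the mean collapsed log2 fold change over the kinase's m
measured substrate sites and (u, sd) are the mean and standard deviation
of all measured site fold changes in the contrast — the substrate set is
compared against the overall fold-change distribution of the sample. A
two-tailed normal test gives the p value. By construction z is invariant
to shifting all fold changes by a constant or scaling them by c > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .quant import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FcBackground:
    """Overall fold-change distribution of one contrast."""

    u: float  # mean of all measured site log2FCs
    sd: float  # sample standard deviation (ddof=1)
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("background needs >= 2 finite fold changes")
        # tolerance absorbs rounding residue of identical fold changes
        if not self.sd > 1e-12:
            raise ValueError("degenerate background: sd must be > 0")


@dataclass(frozen=True)
class KinaseActivity:
    kinase: str
    condition: str
    timepoint: str
    m: int  # measured substrate sites
    M: float  # mean substrate log2FC
    u: float  # background mean
    se: float  # background sd / sqrt(m)
    z: float
    p: float


def _contrast_slice(site_fc: pd.DataFrame, condition: str, timepoint: str) -> pd.DataFrame:
    sel = site_fc[
        (site_fc["condition"] == condition)
        & (site_fc["timepoint"].astype(str) == str(timepoint))
    ]
    return sel[np.isfinite(sel["fc"])]


def compute_background(
    site_fc: pd.DataFrame, condition: str, timepoint: str
) -> FcBackground:
    """Mean/SD of all finite collapsed site fold changes in one contrast."""
    fcs = _contrast_slice(site_fc, condition, timepoint)["fc"].to_numpy(float)
    if fcs.size < 2:
        raise ValueError(
            f"contrast {condition}/{timepoint}: need >= 2 finite fold changes"
        )
    return FcBackground(
        u=float(np.mean(fcs)), sd=float(np.std(fcs, ddof=1)), n_total=int(fcs.size)
    )


def kinase_z(
    kinase: str,
    site_fc: pd.DataFrame,
    background: FcBackground,
    substrates: set[tuple[str, int]],
    condition: str,
    timepoint: str,
    use_substrate_sd: bool = False,
) -> KinaseActivity | None:
    """Activity z score of one kinase in one contrast, or None if fewer
    than two of its annotated substrate sites were measured.

    A multiply-phosphorylated site group contributes once even if several
    of its positions are annotated substrates of the kinase.
    ``use_substrate_sd`` switches the standard error to the substrate-set
    SD instead of the background SD.
    """
    sel = _contrast_slice(site_fc, condition, timepoint)
    hit = sel[[k in substrates for k in zip(sel["protein"], sel["position"].astype(int))]]
    if "site_key" in hit.columns:
        hit = hit.sort_values(["site_key", "protein", "position"]).drop_duplicates(
            subset=["site_key"], keep="first"
        )
    m = len(hit)
    if m < 2:
        logger.debug("kinase %s skipped: %d measured substrates (< 2)", kinase, m)
        return None
    fcs = hit["fc"].to_numpy(float)
    M = float(np.mean(fcs))
    if use_substrate_sd:
        sd = float(np.std(fcs, ddof=1))
        if not sd > 0:
            sd = background.sd
    else:
        sd = background.sd
    se = sd / np.sqrt(m)
    z = (M - background.u) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return KinaseActivity(
        kinase=kinase,
        condition=condition,
        timepoint=str(timepoint),
        m=m,
        M=M,
        u=background.u,
        se=float(se),
        z=float(z),
        p=p,
    )


def infer_activities(
    site_fc: pd.DataFrame,
    annotation: dict[str, set[tuple[str, int]]],
    min_substrates: int = 2,
    alpha: float = 0.05,
    use_substrate_sd: bool = False,
) -> pd.DataFrame:
    """Kinase activity table over every contrast present in the FC table.

    One row per (kinase, contrast) with at least ``min_substrates``
    measured substrate sites; kinases below the floor are omitted, not
    zero-filled. Columns: kinase, condition, timepoint, m, M, u, se, z, p,
    adj_p (BH within contrast), significant (raw p < alpha, matching the
    unadjusted z-test cutoff convention).
    """
    if not annotation:
        raise ValueError("empty kinase-substrate annotation")
    contrasts = (
        site_fc[["condition", "timepoint"]]
        .astype({"timepoint": str})
        .drop_duplicates()
        .sort_values(["condition", "timepoint"])
        .itertuples(index=False)
    )
    rows: list[KinaseActivity] = []
    for condition, timepoint in contrasts:
        bg = compute_background(site_fc, condition, timepoint)
        for kin in sorted(annotation):
            act = kinase_z(
                kin,
                site_fc,
                bg,
                annotation[kin],
                condition,
                timepoint,
                use_substrate_sd=use_substrate_sd,
            )
            if act is not None and act.m >= min_substrates:
                rows.append(act)
    if not rows:
        logger.info("infer_activities: no kinase reached %d measured substrates", min_substrates)
        return pd.DataFrame(
            columns=["kinase", "condition", "timepoint", "m", "M", "u", "se", "z", "p", "adj_p", "significant"]
        )
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["adj_p"] = np.nan
    for (cond, tp), idx in out.groupby(["condition", "timepoint"]).groups.items():
        out.loc[idx, "adj_p"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["p"] < alpha
    return out


def contrast_deltas(
    activities: pd.DataFrame, ligand_a: str, ligand_b: str
) -> pd.DataFrame:
    """Per-timepoint z differences between two stimulation conditions.

    The display statistic for differentially regulated kinases: dz =
    z(ligand_a) - z(ligand_b) for every kinase scored in both conditions
    at a timepoint.
    """
    a = activities[activities["condition"] == ligand_a]
    b = activities[activities["condition"] == ligand_b]
    merged = a.merge(
        b, on=["kinase", "timepoint"], suffixes=("_a", "_b")
    )[["kinase", "timepoint", "z_a", "z_b"]]
    merged["dz"] = merged["z_a"] - merged["z_b"]
    return merged.sort_values(["timepoint", "dz"], ascending=[True, False]).reset_index(
        drop=True
    )


def read_ks_annotation(path: str | Path) -> dict[str, set[tuple[str, int]]]:
    """Read a 3-column kinase-substrate TSV (kinase, protein, site e.g. S473)."""
    df = pd.read_csv(path, sep="\t")
    required = {"kinase", "protein", "site"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    out: dict[str, set[tuple[str, int]]] = {}
    for kin, prot, site in zip(df["kinase"], df["protein"], df["site"]):
        pos = int(str(site)[1:])
        if pos < 1:
            raise ValueError(f"invalid substrate site {site!r}")
        out.setdefault(kin, set()).add((prot, pos))
    return out


def annotation_from_frame(df: pd.DataFrame) -> dict[str, set[tuple[str, int]]]:
    """Convert a (kinase, protein, site) frame to the lookup used here."""
    out: dict[str, set[tuple[str, int]]] = {}
    for kin, prot, site in zip(df["kinase"], df["protein"], df["site"]):
        out.setdefault(kin, set()).add((prot, int(str(site)[1:])))
    return out
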