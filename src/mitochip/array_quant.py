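"""Spike-in-calibrated quantification of single-channel spot tables.

The pipeline mirrors absolute quantification on a spotted oligo array with
reference (spike-in) control spots of known amount printed alongside the
gene probes:

1. per-spot net signal = foreground mean − local background (negative
   values become missing),
2. saturated spots (foreground at the detector ceiling) are excluded —
   both from the calibration fit and from gene quantification,
3. an ordinary least-squares calibration line of net signal vs known spike
   amount converts each slide's signals into pg-equivalents
   (abundance = net signal / slope); with a fixed RNA input per
   hybridization this reads as abundance per µg of RNA,
4. replicate slides of the same sample are median-corrected
   (multiplicatively rescaled to the grand median) and averaged,
5. abundances are expressed as log2 ratios against a reference tissue and
   tissue effects are tested per gene with a two-way (gene × tissue)
   fixed-effects ANOVA on log2 abundances, flagged at p < 0.05
   (unadjusted by default; Benjamini–Hochberg available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SPOT_COLUMNS = [
    "slide_id", "block", "probe_id", "spot_class", "fg_mean", "bg_local",
    "known_amount_pg",
]

DEFAULT_SATURATION_FRAC = 0.95


class CalibrationError(ValueError):
    """Raised when a slide's spike-in calibration cannot be fitted."""


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line of net signal vs known spike amount: a slide's quantification scale."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    excluded_saturated: tuple[str, ...] = ()
    valid_range: tuple[float, float] = (np.nan, np.nan)


@dataclass
class AbundanceResult:
    """End-to-end quantification output.

    ``abundance`` is a long table (probe_id, tissue, fraction, mean, sd, n,
    quantifiable); ``replicates`` holds the median-corrected per-slide
    values; ``ratios`` the per-fraction log2 ratio matrices vs the
    reference tissue; ``anova`` the per-gene tissue contrasts.
    """

    abundance: pd.DataFrame
    replicates: pd.DataFrame
    calibrations: dict[str, CalibrationFit] = field(default_factory=dict)
    ratios: dict[str, pd.DataFrame] = field(default_factory=dict)
    anova: dict[str, pd.DataFrame] = field(default_factory=dict)


def net_signal(fg_mean: float, bg_local: float) -> float:
    """Local-background-subtracted signal; negative results are missing."""
    net = fg_mean - bg_local
    return net if net >= 0 else np.nan


def net_signal_frame(df: pd.DataFrame) -> pd.Series:
    net = df["fg_mean"] - df["bg_local"]
    n_neg = int((net < 0).sum())
    if n_neg:
        logger.info("%d spots with background above foreground set missing", n_neg)
    return net.mask(net < 0)


def flag_saturated(
    fg_mean: pd.Series | np.ndarray,
    detector_max: float,
    frac: float = DEFAULT_SATURATION_FRAC,
) -> pd.Series | np.ndarray:
    """True for spots whose foreground reaches ``frac`` of the detector ceiling."""
    if detector_max <= 0:
        raise ValueError("detector_max must be positive")
    return fg_mean >= frac * detector_max


def fit_calibration(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    excluded_saturated: Sequence[str] = (),
) -> CalibrationFit:
    """Least-squares calibration line of net signal vs spike amount (pg).

    Requires at least three usable points spanning at least two distinct
    amounts and a positive slope; otherwise the slide is rejected with a
    :class:`CalibrationError` so that bad slides never propagate silently.
    """
    if isinstance(points, pd.DataFrame):
        amounts = points["known_amount_pg"].to_numpy(float)
        signals = points["net"].to_numpy(float)
    else:
        arr = np.asarray(points, dtype=float)
        amounts, signals = (arr[:, 0], arr[:, 1]) if arr.size else (
            np.array([]), np.array([])
        )
    keep = np.isfinite(amounts) & np.isfinite(signals)
    amounts, signals = amounts[keep], signals[keep]
    if len(amounts) < 3 or len(np.unique(amounts)) < 2:
        raise CalibrationError(
            f"calibration needs >=3 points over >=2 amounts; got "
            f"{len(amounts)} points"
        )
    fit = stats.linregress(amounts, signals)
    if fit.slope <= 0:
        raise CalibrationError(f"non-positive calibration slope {fit.slope:.4g}")
    return CalibrationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=int(len(amounts)),
        excluded_saturated=tuple(excluded_saturated),
        valid_range=(float(amounts.min()), float(amounts.max())),
    )


def normalize_slide(net: pd.Series, fit: CalibrationFit) -> pd.Series:
    """Convert net signals into pg-equivalents by dividing by the slope."""
    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return net / fit.slope


def quantify_slide(
    slide: pd.DataFrame,
    detector_max: float,
    saturation_frac: float = DEFAULT_SATURATION_FRAC,
) -> tuple[pd.Series, CalibrationFit]:
    """One slide's per-probe abundance (pg-equivalents) and calibration fit.

    Saturated calibration spots are excluded from the fit; saturated gene
    spots become missing.  The six replicate blocks of a slide are averaged
    (mean of usable spots per probe).
    """
    df = slide.copy()
    df["net"] = net_signal_frame(df)
    saturated = flag_saturated(df["fg_mean"], detector_max, saturation_frac)

    cal = df[df["spot_class"] == "calibration"]
    cal_sat = saturated[cal.index]
    excluded = [
        f"{row.probe_id}/block{row.block}"
        for row in cal[cal_sat].itertuples()
    ]
    fit = fit_calibration(cal[~cal_sat], excluded_saturated=excluded)

    genes = df[df["spot_class"] == "gene"].copy()
    genes.loc[saturated[genes.index], "net"] = np.nan
    genes["abundance"] = normalize_slide(genes["net"], fit)
    per_probe = genes.groupby("probe_id")["abundance"].mean()
    return per_probe, fit


def median_correct(replicates: pd.DataFrame) -> pd.DataFrame:
    """Rescale each replicate column so its median equals the grand median.

    The grand median is the median of the per-replicate medians; scaling is
    multiplicative so abundances stay non-negative.  A single replicate is
    returned unchanged; all-missing replicates are dropped with a warning.
    """
    mat = replicates.copy()
    usable = [c for c in mat.columns if mat[c].notna().any()]
    dropped = [c for c in mat.columns if c not in usable]
    if dropped:
        logger.warning("dropping all-missing replicates: %s", dropped)
    mat = mat[usable]
    if mat.shape[1] <= 1:
        return mat
    medians = mat.median(axis=0, skipna=True)
    grand = float(medians.median())
    for col in mat.columns:
        med = medians[col]
        if med > 0:
            mat[col] = mat[col] * (grand / med)
        else:
            logger.warning("replicate %s has non-positive median; left unscaled", col)
    return mat


def summarize_abundance(corrected: pd.DataFrame, min_fraction_present: float = 0.5
                        ) -> pd.DataFrame:
    """Per-probe mean, SD and n across replicate columns.

    A probe missing in more than ``1 - min_fraction_present`` of the
    replicates is reported not-quantifiable (mean/sd set missing).
    """
    n_rep = corrected.shape[1]
    out = pd.DataFrame(
        {
            "mean": corrected.mean(axis=1, skipna=True),
            "sd": corrected.std(axis=1, ddof=1, skipna=True),
            "n": corrected.notna().sum(axis=1),
        }
    )
    out["quantifiable"] = out["n"] >= min_fraction_present * n_rep
    out.loc[~out["quantifiable"], ["mean", "sd"]] = np.nan
    return out


def log2_ratio_table(matrix: pd.DataFrame, reference_tissue: str) -> pd.DataFrame:
    """log2 of each tissue column against the reference column.

    The reference column is identically zero; zero or missing denominators
    yield missing ratios.
    """
    if reference_tissue not in matrix.columns:
        raise KeyError(f"reference tissue {reference_tissue!r} not in matrix")
    ref = matrix[reference_tissue].where(matrix[reference_tissue] > 0)
    n_bad = int(ref.isna().sum() - matrix[reference_tissue].isna().sum())
    if n_bad:
        logger.info("%d genes with zero reference abundance set missing", n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(matrix.div(ref, axis=0))
    ratios = ratios.replace([np.inf, -np.inf], np.nan)
    ratios[reference_tissue] = np.where(ref.notna(), 0.0, np.nan)
    return ratios


def two_way_anova(
    long_df: pd.DataFrame,
    reference_tissue: str,
    alpha: float = 0.05,
    adjust: str | None = None,
    value_col: str = "value",
) -> pd.DataFrame:
    """Per-gene tissue contrasts from a gene × tissue fixed-effects ANOVA.

    ``long_df`` has one row per replicate observation with columns
    ``gene``, ``tissue`` and ``value_col`` (abundances on the linear
    scale; log2-transformed here before testing).  A cell-means model over
    the gene × tissue cells is fitted; the pooled within-cell variance
    provides the error term, and each (gene, tissue) cell is contrasted
    against the gene's reference-tissue cell with a t test.  p-values are
    unadjusted unless ``adjust='bh'`` (Benjamini–Hochberg).

    Degenerate data (zero pooled variance, e.g. constant values) yields no
    finite statistic: all contrasts are reported not-significant with a
    ``degenerate`` flag.  Cells without observations are skipped with a
    ``missing_cell`` flag.
    """
    df = long_df[["gene", "tissue", value_col]].copy()
    df = df[np.isfinite(df[value_col]) & (df[value_col] > 0)]
    df["log2"] = np.log2(df[value_col])

    cells = df.groupby(["gene", "tissue"])["log2"].agg(["mean", "var", "count"])
    n_cells = len(cells)
    n_obs = int(cells["count"].sum())
    df_error = n_obs - n_cells
    ss_within = float(
        ((cells["count"] - 1) * cells["var"].fillna(0.0)).sum()
    )
    mse = ss_within / df_error if df_error > 0 else np.nan
    degenerate = not np.isfinite(mse) or mse <= 0

    rows = []
    genes = sorted(df["gene"].unique())
    tissues = sorted(df["tissue"].unique())
    for gene in genes:
        has_ref = (gene, reference_tissue) in cells.index
        for tissue in tissues:
            if tissue == reference_tissue:
                continue
            flag = ""
            est = t_stat = p = np.nan
            if not has_ref or (gene, tissue) not in cells.index:
                flag = "missing_cell"
            else:
                m1, _, n1 = cells.loc[(gene, tissue)]
                m0, _, n0 = cells.loc[(gene, reference_tissue)]
                est = m1 - m0
                if degenerate:
                    flag = "degenerate"
                else:
                    se = np.sqrt(mse * (1.0 / n1 + 1.0 / n0))
                    if se > 0:
                        t_stat = est / se
                        p = 2.0 * stats.t.sf(abs(t_stat), df_error)
                    else:
                        flag = "degenerate"
            rows.append(
                {
                    "gene": gene, "tissue": tissue, "log2_diff": est,
                    "t": t_stat, "p": p, "flag": flag,
                }
            )
    out = pd.DataFrame(rows)
    if adjust == "bh" and out["p"].notna().any():
        from statsmodels.stats.multitest import multipletests

        mask = out["p"].notna()
        out.loc[mask, "p_adj"] = multipletests(
            out.loc[mask, "p"], method="fdr_bh"
        )[1]
        out["significant"] = out.get("p_adj", pd.Series(np.nan)) < alpha
    else:
        out["significant"] = out["p"] < alpha
    out["significant"] = out["significant"].fillna(False).astype(bool)
    return out


def anova_global_table(long_df: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Classical two-way ANOVA table (gene, tissue, interaction) via statsmodels."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = long_df[["gene", "tissue", value_col]].copy()
    df = df[np.isfinite(df[value_col]) & (df[value_col] > 0)]
    df["log2"] = np.log2(df[value_col])
    model = smf.ols("log2 ~ C(gene) * C(tissue)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def quantify_experiment(
    spots: pd.DataFrame,
    design: pd.DataFrame,
    detector_max: float,
    reference_tissue: str | None = None,
    saturation_frac: float = DEFAULT_SATURATION_FRAC,
    probe_quantifiable: Mapping[str, bool] | None = None,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> AbundanceResult:
    """Run the full pipeline over a multi-slide experiment.

    ``spots`` follows the spot CSV schema; ``design`` maps each slide_id to
    (tissue, fraction, replicate).  Slides failing calibration are dropped
    with a warning.  Probes marked non-quantifiable (tRNA/rRNA) are removed
    before summarization.
    """
    design = design.set_index("slide_id") if "slide_id" in design.columns else design
    per_slide: dict[str, pd.Series] = {}
    calibrations: dict[str, CalibrationFit] = {}
    for slide_id, slide in spots.groupby("slide_id"):
        try:
            abundance, fit = quantify_slide(slide, detector_max, saturation_frac)
        except CalibrationError as exc:
            logger.warning("slide %s rejected: %s", slide_id, exc)
            continue
        per_slide[str(slide_id)] = abundance
        calibrations[str(slide_id)] = fit

    rep_frames = []
    summaries = []
    long_rows: dict[str, list[pd.DataFrame]] = {}
    groups: dict[tuple[str, str], list[str]] = {}
    for slide_id in per_slide:
        tissue = design.loc[slide_id, "tissue"]
        fraction = design.loc[slide_id, "fraction"]
        groups.setdefault((str(tissue), str(fraction)), []).append(slide_id)

    for (tissue, fraction), slide_ids in sorted(groups.items()):
        mat = pd.DataFrame({sid: per_slide[sid] for sid in slide_ids})
        if probe_quantifiable is not None:
            keep = [p for p in mat.index if probe_quantifiable.get(p, True)]
            mat = mat.loc[keep]
        corrected = median_correct(mat)
        summary = summarize_abundance(corrected)
        summary.insert(0, "tissue", tissue)
        summary.insert(1, "fraction", fraction)
        summaries.append(summary.reset_index(names="probe_id"))

        rep_long = corrected.reset_index(names="probe_id").melt(
            id_vars="probe_id", var_name="slide_id", value_name="value"
        )
        rep_long.insert(1, "tissue", tissue)
        rep_long.insert(2, "fraction", fraction)
        rep_frames.append(rep_long)
        long_rows.setdefault(fraction, []).append(
            rep_long.rename(columns={"probe_id": "gene"})
        )

    abundance = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    replicates = pd.concat(rep_frames, ignore_index=True) if rep_frames else pd.DataFrame()

    ratios: dict[str, pd.DataFrame] = {}
    anova: dict[str, pd.DataFrame] = {}
    if reference_tissue is not None and not abundance.empty:
        for fraction, frames in long_rows.items():
            wide = (
                abundance[abundance["fraction"] == fraction]
                .pivot(index="probe_id", columns="tissue", values="mean")
            )
            if reference_tissue in wide.columns:
                ratios[fraction] = log2_ratio_table(wide, reference_tissue)
                long_df = pd.concat(frames, ignore_index=True)
                anova[fraction] = two_way_anova(
                    long_df, reference_tissue, alpha=alpha, adjust=adjust
                )
            else:
                logger.warning(
                    "reference tissue %r absent for fraction %r; skipping "
                    "ratios/ANOVA", reference_tissue, fraction,
                )
    return AbundanceResult(
        abundance=abundance, replicates=replicates, calibrations=calibrations,
        ratios=ratios, anova=anova,
    )


def read_spot_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing spot columns {sorted(missing)}")
    bad = df[(df["spot_class"] == "calibration") & df["known_amount_pg"].isna()]
    if len(bad):
        raise ValueError(f"{path}: calibration spots without known_amount_pg")
    return df


def write_abundance_tsv(path: str | Path, result: AbundanceResult) -> None:
    result.abundance.to_csv(path, sep="\t", index=False, float_format="%.6g")
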