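"""Gradient-fraction and qPCR CT analysis.

Sucrose-gradient runs are collected as ten equal-volume fractions, light
to heavy.  Free (non-polysomal) mRNA sediments in fractions 1–5 and
ribosome-bound mRNA in fractions 6–10; the bound/free signal ratio is the
polysome-loading readout.  Puromycin dissociates ribosomes from mRNA, so
a treated aliquot must shift bound signal into the light fractions — the
negative control for the partition.

CT summaries follow the usual ΔCT conventions: mitochondrial-DNA content
per nuclear genome as the difference of mitochondrial and nuclear CTs
(sign convention configurable), and expression as 40 − ΔCT against the
mean of reference-gene CTs (one cycle ≈ two-fold).  Perfect primer
efficiency is assumed; efficiency correction is out of scope and noted in
output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

N_FRACTIONS = 10
#: fractions holding free mRNA (1-based labels 1..5) and ribosome-bound mRNA (6..10)
FREE_FRACTIONS = (1, 2, 3, 4, 5)
BOUND_FRACTIONS = (6, 7, 8, 9, 10)


@dataclass(frozen=True)
class GradientProfile:
    """Per-gene signal across the ten gradient fractions."""

    gene: str
    tissue: str
    intensities: tuple[float, ...]
    treatment: str = "none"  # none | puromycin

    def __post_init__(self) -> None:
        if len(self.intensities) != N_FRACTIONS:
            raise ValueError(
                f"{self.gene}/{self.tissue}: expected {N_FRACTIONS} fractions, "
                f"got {len(self.intensities)}"
            )
        if any(x < 0 for x in self.intensities):
            raise ValueError(f"{self.gene}/{self.tissue}: negative intensity")
        if self.treatment not in ("none", "puromycin"):
            raise ValueError(f"bad treatment {self.treatment!r}")


@dataclass(frozen=True)
class LoadingSummary:
    """Free/bound partition of one gradient profile.

    ``loading_ratio`` is bound/free; when the free signal is zero the
    ratio is not a number and ``ratio_infinite`` is set instead.
    """

    gene: str
    tissue: str
    free_signal: float
    bound_signal: float
    loading_ratio: float
    ratio_infinite: bool

    @property
    def bound_share(self) -> float:
        total = self.free_signal + self.bound_signal
        return self.bound_signal / total if total > 0 else math.nan


@dataclass(frozen=True)
class PuromycinControl:
    """Outcome of the puromycin dissociation control for one gene/tissue."""

    gene: str
    tissue: str
    passed: bool | None  # None when not evaluable
    shift: float  # bound share (untreated) - bound share (puromycin)


def partition_profile(profile: GradientProfile) -> LoadingSummary:
    """Split a 10-fraction profile into free (1–5) and bound (6–10) signal."""
    free = float(sum(profile.intensities[:5]))
    bound = float(sum(profile.intensities[5:]))
    infinite = free == 0.0
    ratio = math.nan if infinite else bound / free
    return LoadingSummary(
        gene=profile.gene, tissue=profile.tissue, free_signal=free,
        bound_signal=bound, loading_ratio=ratio, ratio_infinite=infinite,
    )


def puromycin_control(
    untreated: GradientProfile | None, treated: GradientProfile | None
) -> PuromycinControl:
    """Check that puromycin moved bound signal into the light fractions.

    The control passes iff the bound-fraction share under puromycin is
    strictly below the untreated bound share; the shift magnitude is the
    difference of bound shares.  Missing counterpart → not evaluable.
    """
    if untreated is None or treated is None:
        ref = untreated or treated
        return PuromycinControl(
            gene=ref.gene if ref else "", tissue=ref.tissue if ref else "",
            passed=None, shift=math.nan,
        )
    if (untreated.gene, untreated.tissue) != (treated.gene, treated.tissue):
        raise ValueError("profiles are for different gene/tissue")
    share_u = partition_profile(untreated).bound_share
    share_p = partition_profile(treated).bound_share
    shift = share_u - share_p
    passed = bool(share_p < share_u) if math.isfinite(shift) else None
    return PuromycinControl(
        gene=untreated.gene, tissue=untreated.tissue, passed=passed,
        shift=shift,
    )


def mito_dna_content(
    ct_mito: float, ct_nuclear: float, convention: str = "mito_minus_nuclear"
) -> float:
    """ΔCT between a mitochondrial and a nuclear genomic region.

    One cycle corresponds to a two-fold template difference; a negative
    mito−nuclear ΔCT means more mitochondrial than nuclear copies.  The
    sign convention is explicit and echoed in serialized output.
    """
    if convention == "mito_minus_nuclear":
        return ct_mito - ct_nuclear
    if convention == "nuclear_minus_mito":
        return ct_nuclear - ct_mito
    raise ValueError(f"unknown convention {convention!r}")


def forty_minus_dct(ct_target: float, ct_refs: Sequence[float]) -> float:
    """Expression score 40 − (CT_target − mean(CT_references)).

    Higher means more abundant; equality with the reference mean gives 40.
    """
    if len(ct_refs) == 0:
        raise ValueError("at least one reference CT is required")
    return 40.0 - (ct_target - float(np.mean(ct_refs)))


# ---------------------------------------------------------------------------
# table-level API

def read_fractions_csv(path: str | Path) -> list[GradientProfile]:
    """Read a fractions table (gene, tissue, treatment, f1..f10)."""
    df = pd.read_csv(path)
    cols = [f"f{i}" for i in range(1, N_FRACTIONS + 1)]
    missing = {"gene", "tissue", "treatment", *cols} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GradientProfile(
            gene=row["gene"], tissue=row["tissue"],
            intensities=tuple(float(row[c]) for c in cols),
            treatment=row["treatment"],
        )
        for _, row in df.iterrows()
    ]


def analyze_gradients(
    profiles: Sequence[GradientProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Loading summaries and puromycin controls for a set of profiles.

    Returns (loading table, controls table).  Loading ratios are computed
    from untreated profiles; controls pair each untreated profile with its
    puromycin counterpart where present.
    """
    by_key: dict[tuple[str, str, str], GradientProfile] = {}
    for p in profiles:
        key = (p.gene, p.tissue, p.treatment)
        if key in by_key:
            raise ValueError(f"duplicate profile for {key}")
        by_key[key] = p

    loading_rows, control_rows = [], []
    for (gene, tissue, treatment), p in sorted(by_key.items()):
        if treatment != "none":
            continue
        s = partition_profile(p)
        loading_rows.append(
            {
                "gene": gene, "tissue": tissue, "free_signal": s.free_signal,
                "bound_signal": s.bound_signal,
                "loading_ratio": s.loading_ratio,
                "ratio_infinite": s.ratio_infinite,
            }
        )
        ctrl = puromycin_control(p, by_key.get((gene, tissue, "puromycin")))
        control_rows.append(
            {
                "gene": gene, "tissue": tissue,
                "puromycin_ok": ctrl.passed, "shift": ctrl.shift,
            }
        )
    return pd.DataFrame(loading_rows), pd.DataFrame(control_rows)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Read a CT table (sample, target, role, ct)."""
    df = pd.read_csv(path)
    missing = {"sample", "target", "role", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        raise ValueError(f"{path}: CT values must be finite and positive")
    return df


def summarize_ct(
    ct: pd.DataFrame,
    reference_targets: Sequence[str] = (),
    convention: str = "mito_minus_nuclear",
) -> pd.DataFrame:
    """Per-sample qPCR summaries from a CT table.

    For samples with ``mito_region`` and ``nuclear_region`` rows, the
    mito-DNA ΔCT is reported.  For each ``target`` row, expression is
    reported as 40 − ΔCT against the mean CT of the reference rows (rows
    with role ``reference``, optionally restricted to
    ``reference_targets``).
    """
    rows = []
    for sample, grp in ct.groupby("sample"):
        refs = grp[grp["role"] == "reference"]
        if reference_targets:
            refs = refs[refs["target"].isin(reference_targets)]
        ref_cts = refs["ct"].tolist()
        mito = grp[grp["role"] == "mito_region"]["ct"]
        nuc = grp[grp["role"] == "nuclear_region"]["ct"]
        if len(mito) and len(nuc):
            rows.append(
                {
                    "sample": sample, "target": "mito_dna",
                    "metric": f"dct_{convention}",
                    "value": mito_dna_content(
                        float(mito.mean()), float(nuc.mean()), convention
                    ),
                }
            )
        for _, row in grp[grp["role"] == "target"].iterrows():
            if ref_cts:
                rows.append(
                    {
                        "sample": sample, "target": row["target"],
                        "metric": "forty_minus_dct",
                        "value": forty_minus_dct(float(row["ct"]), ref_cts),
                    }
                )
    return pd.DataFrame(rows)
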