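"""qPCR standard-curve model and absolute rDNA copy-number quantitation.

The model is the standard-curve line C_T = k * log10(copies uL^-1) + b with
k < 0 (more template crosses threshold earlier). Amplification efficiency
follows from the slope as E = (10^(-1/k) - 1) * 100%; a slope of
-1/log10(2) ~ -3.3219 is perfect per-cycle doubling (100%).

Note on the published assay this toolkit models: its curve is printed with a
positive slope magnitude 3.5187 and intercept 32.035 alongside an efficiency
of 92.4% — the efficiency is only consistent with k = -3.5187, so the slope
is taken as negative throughout.

Copy numbers in template extracts convert to copies per litre of source
water through the volume chain: copies uL^-1 x (extract volume / template
volume) x (1000 / filtered volume in mL).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CladeampError, InsufficientDataError, ValidationError

#: printed magnitudes of the published standard curve, usable as generator truth
PUBLISHED_SLOPE = -3.5187
PUBLISHED_INTERCEPT = 32.035


@dataclass(frozen=True)
class DilutionPoint:
    """One well of a standard dilution series."""

    copies_per_ul: float
    ct: float
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.copies_per_ul <= 0:
            raise ValidationError("copies_per_ul must be > 0")
        if self.ct <= 0:
            raise ValidationError("ct must be > 0")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted line C_T = slope * log10(copies uL^-1) + intercept."""

    slope: float
    intercept: float
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValidationError(f"r2 must lie in [0, 1], got {self.r2}")
        if self.slope >= 0:
            warnings.warn(
                "standard-curve slope is non-negative; C_T should decrease "
                "with template amount",
                stacklevel=3,
            )


@dataclass(frozen=True)
class AssayConstants:
    """Physical constants for converting standard mass to molecule counts."""

    bp_molecular_weight: float = 660.0  # g mol^-1 bp^-1, double-stranded
    avogadro: float = 6.022e23  # mol^-1
    standard_fragment_length: int = 1775  # bp, the assay's linear standard

    def __post_init__(self) -> None:
        if min(self.bp_molecular_weight, self.avogadro, self.standard_fragment_length) <= 0:
            raise ValidationError("assay constants must be strictly positive")


@dataclass(frozen=True)
class QuantResult:
    """Absolute quantitation of one environmental sample."""

    sample: str
    ct: float
    copies_per_ul_template: float
    copies_per_liter_source: float
    template_vol_ul: float
    extract_vol_ul: float
    filtered_vol_ml: float
    below_detection: bool = False


def fit_standard_curve(
    points: Sequence[DilutionPoint], average_replicates: bool = True
) -> StandardCurve:
    """Ordinary least squares of C_T on log10(copies uL^-1).

    Replicate wells at the same dilution level are averaged before fitting
    by default; ``average_replicates=False`` pools all wells. Needs at least
    three distinct dilution levels.
    """
    if not points:
        raise InsufficientDataError("no dilution points")
    df = pd.DataFrame(
        {"copies": [p.copies_per_ul for p in points], "ct": [p.ct for p in points]}
    )
    df["log10_copies"] = np.log10(df["copies"])
    n_levels = df["log10_copies"].round(9).nunique()
    if n_levels < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct dilution levels, got {n_levels}"
        )
    if average_replicates:
        df = df.groupby("log10_copies", as_index=False)["ct"].mean()
    if np.isclose(df["log10_copies"].var(), 0.0):
        raise InsufficientDataError("zero variance in log10 copies (degenerate design)")
    fit = stats.linregress(df["log10_copies"], df["ct"])
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r2=min(float(fit.rvalue) ** 2, 1.0))


def efficiency(slope: float) -> float:
    """Amplification efficiency in percent from the standard-curve slope:
    E = (10^(-1/k) - 1) * 100 with k < 0.

    A positive slope is interpreted as a sign slip and negated (with a
    warning); zero is a domain error.
    """
    if slope == 0:
        raise CladeampError("slope must be nonzero")
    k = slope
    if k > 0:
        warnings.warn("positive slope passed to efficiency(); using its negative",
                      stacklevel=2)
        k = -k
    return (10.0 ** (-1.0 / k) - 1.0) * 100.0


def molecules_per_ul(
    concentration_g_per_ul: float,
    fragment_length_bp: float | None = None,
    constants: AssayConstants = AssayConstants(),
) -> float:
    """Copies per microlitre of a linear standard from its mass concentration:
    a / (L x 660) x 6.022e23, with L the fragment length in bp."""
    L = fragment_length_bp if fragment_length_bp is not None else constants.standard_fragment_length
    if concentration_g_per_ul <= 0 or L <= 0:
        raise CladeampError("concentration and fragment length must be > 0")
    return (
        concentration_g_per_ul / (L * constants.bp_molecular_weight) * constants.avogadro
    )


def ct_to_copies(curve: StandardCurve, ct: float) -> float:
    """Invert the fitted line: copies uL^-1 = 10^((ct - b) / k)."""
    if curve.slope >= 0:
        raise ValidationError("curve slope must be negative to invert")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def copies_per_liter(
    copies_per_ul_template: float,
    template_vol_ul: float,
    extract_vol_ul: float,
    filtered_vol_ml: float,
) -> float:
    """Scale template-reaction copies up through the extraction/filtration
    volume chain to copies per litre of source water."""
    if min(template_vol_ul, extract_vol_ul, filtered_vol_ml) <= 0:
        raise CladeampError("all volumes must be > 0")
    if copies_per_ul_template < 0:
        raise CladeampError("copies must be >= 0")
    return (
        copies_per_ul_template
        * (extract_vol_ul / template_vol_ul)
        * (1000.0 / filtered_vol_ml)
    )


def detection_limit_cells(min_detectable_copies: float, copies_per_cell: float) -> float:
    """Detection limit expressed in cell equivalents (e.g. 96 rDNA copies at
    160,000 copies per cell = 0.0006 cells)."""
    if copies_per_cell <= 0:
        raise CladeampError("copies_per_cell must be > 0")
    if min_detectable_copies < 0:
        raise CladeampError("min_detectable_copies must be >= 0")
    return min_detectable_copies / copies_per_cell


def quantify_sample(
    curve: StandardCurve,
    sample: str,
    ct: float,
    template_vol_ul: float,
    extract_vol_ul: float,
    filtered_vol_ml: float,
    lod_ct: float | None = None,
) -> QuantResult:
    """Absolute quantitation of one sample C_T through the fitted curve.

    ``lod_ct`` is the C_T of the faintest reliably detected standard; a
    sample C_T beyond it is flagged below-detection (its nominal copy number
    is still reported).
    """
    copies = ct_to_copies(curve, ct)
    return QuantResult(
        sample=sample,
        ct=ct,
        copies_per_ul_template=copies,
        copies_per_liter_source=copies_per_liter(
            copies, template_vol_ul, extract_vol_ul, filtered_vol_ml
        ),
        template_vol_ul=template_vol_ul,
        extract_vol_ul=extract_vol_ul,
        filtered_vol_ml=filtered_vol_ml,
        below_detection=(lod_ct is not None and ct > lod_ct),
    )


def read_dilution_series(path: str | Path) -> list[DilutionPoint]:
    """Dilution series from delimited text with header columns
    copies_per_ul, ct[, replicate]."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "copies_per_ul" not in cols or "ct" not in cols:
        raise ValidationError("need columns 'copies_per_ul' and 'ct'")
    rep = cols.get("replicate")
    return [
        DilutionPoint(
            float(row[cols["copies_per_ul"]]),
            float(row[cols["ct"]]),
            str(row[rep]) if rep else "r1",
        )
        for _, row in df.iterrows()
    ]


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Sample C_T table: sample, ct, replicate, template_vol_ul,
    extract_vol_ul, filtered_vol_ml."""
    df = pd.read_csv(path, sep=None, engine="python")
    needed = {"sample", "ct", "template_vol_ul", "extract_vol_ul", "filtered_vol_ml"}
    missing = needed - {c.lower() for c in df.columns}
    if missing:
        raise ValidationError(f"sample table missing columns: {sorted(missing)}")
    df.columns = [c.lower() for c in df.columns]
    return df


def quantify_table(
    curve: StandardCurve, samples: pd.DataFrame, lod_ct: float | None = None
) -> list[QuantResult]:
    """Quantify every row of a sample table (replicate C_T values averaged
    per sample first)."""
    grouped = samples.groupby("sample", sort=True)
    out = []
    for sample, grp in grouped:
        out.append(
            quantify_sample(
                curve,
                str(sample),
                float(grp["ct"].mean()),
                float(grp["template_vol_ul"].iloc[0]),
                float(grp["extract_vol_ul"].iloc[0]),
                float(grp["filtered_vol_ml"].iloc[0]),
                lod_ct=lod_ct,
            )
        )
    return out


def write_quant_results(results: Iterable[QuantResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample\tct\tcopies_per_ul_template\tcopies_per_liter_source\t"
            "below_detection\n"
        )
        for r in results:
            fh.write(
                f"{r.sample}\t{r.ct:.3f}\t{r.copies_per_ul_template:.6g}\t"
                f"{r.copies_per_liter_source:.6g}\t{str(r.below_detection).lower()}\n"
            )
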