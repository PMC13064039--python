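"""Domain types, CSV ingestion, inner-filter correction, and peak utilities.

The central object is the :class:`TitrationSeries`: a fixed amount of protein
(here serum albumin at 2 µM) titrated with increasing quencher (ligand)
concentration at constant temperature, recording the intrinsic fluorescence at
a fixed emission wavelength. All downstream analyses — Stern–Volmer quenching,
double-logarithmic binding fits, van't Hoff thermodynamics — consume this
object. Spectra (emission, synchronous, FTIR, UV-vis) are carried by the
generic :class:`Spectrum` container.

Concentrations are stored internally in mol·L⁻¹; the CSV dialect uses µM
(the unit experimental tables are written in) unless overridden.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisError",
    "TitrationPoint",
    "TitrationSeries",
    "Spectrum",
    "PeakResult",
    "ShiftRecord",
    "CONC_UNIT_SCALES",
    "read_titration_csv",
    "write_titration_csv",
    "read_spectra_csv",
    "write_spectra_csv",
    "correct_inner_filter",
    "correct_series",
    "locate_peak",
    "peak_shift",
]


class AnalysisError(ValueError):
    """Raised when an input violates a precondition of an analysis step."""


#: scale factors converting a concentration column to mol·L⁻¹
CONC_UNIT_SCALES = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}

#: axis kinds measured in nanometres (red/blue shift convention applies directly)
_NM_AXES = {"emission_nm", "synchronous_nm", "uv_nm"}
_AXIS_KINDS = _NM_AXES | {"ftir_wavenumber"}


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: quencher concentration and observed fluorescence.

    Parameters
    ----------
    quencher_conc
        Quencher (ligand) concentration in mol·L⁻¹.
    f_obs
        Fluorescence intensity (arbitrary units). After inner-filter
        correction this holds the corrected value and ``f_raw`` the original.
    a_ex, a_em
        Solution absorbance at the excitation / emission wavelength
        (dimensionless, decadic); optional.
    f_raw
        The uncorrected intensity, populated by :func:`correct_series`.
    """

    quencher_conc: float
    f_obs: float
    a_ex: float | None = None
    a_em: float | None = None
    f_raw: float | None = None

    def __post_init__(self) -> None:
        if self.quencher_conc < 0 or self.f_obs < 0:
            raise AnalysisError("invalid measurement: negative value")
        for a in (self.a_ex, self.a_em):
            if a is not None and a < 0:
                raise AnalysisError("invalid absorbance")

    @property
    def has_absorbances(self) -> bool:
        return self.a_ex is not None and self.a_em is not None


@dataclass
class TitrationSeries:
    """Ordered titration points at one temperature.

    The point at zero quencher concentration supplies the unquenched
    reference intensity F₀; regressions require at least three points.
    """

    points: list[TitrationPoint]
    temperature: float = 303.0
    lambda_ex: float = 279.0
    lambda_em: float = 341.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise AnalysisError("temperature must be positive (kelvin)")
        self.points = sorted(self.points, key=lambda p: p.quencher_conc)
        concs = [p.quencher_conc for p in self.points]
        if len(set(concs)) != len(concs):
            raise AnalysisError("ambiguous titration point: duplicate concentration")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.quencher_conc for p in self.points])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.f_obs for p in self.points])

    @property
    def f0(self) -> float:
        """Reference intensity: the (unique) point at [Q] = 0."""
        zeros = [p for p in self.points if p.quencher_conc == 0.0]
        if not zeros:
            raise AnalysisError("no reference point: series lacks a [Q]=0 row")
        return zeros[0].f_obs


@dataclass
class Spectrum:
    """A 1-D spectrum on a strictly monotone axis.

    ``axis_kind`` is one of ``emission_nm``, ``synchronous_nm``, ``uv_nm``
    or ``ftir_wavenumber``; ``meta`` carries the quencher concentration
    (mol·L⁻¹) or a free-text label of the titration point it belongs to.
    """

    axis_kind: str
    axis: np.ndarray
    intensity: np.ndarray
    meta: float | str | None = None

    def __post_init__(self) -> None:
        if self.axis_kind not in _AXIS_KINDS:
            raise AnalysisError(f"unknown axis kind: {self.axis_kind!r}")
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.size != self.intensity.size:
            raise AnalysisError("axis and intensity lengths differ")
        d = np.diff(self.axis)
        if self.axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise AnalysisError("axis must be strictly monotone")
        if np.any(self.intensity < 0):
            raise AnalysisError("invalid measurement: negative intensity")


@dataclass(frozen=True)
class PeakResult:
    """Location of a band maximum inside a search window."""

    position: float
    height: float
    window: tuple[float, float]
    axis_kind: str
    grid_step: float
    flat: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (lo <= self.position <= hi):
            raise AnalysisError("peak position outside its window")


@dataclass(frozen=True)
class ShiftRecord:
    """Signed peak displacement (treated − reference) with a direction label.

    On nanometre axes a positive shift is "red" (toward longer wavelength).
    On wavenumber axes the energy ordering is reversed, so a *negative*
    cm⁻¹ shift is labelled "red". Shifts below the resolution threshold
    (default: half the grid step) are labelled "none".
    """

    shift: float
    direction: str
    threshold: float
    axis_kind: str


# ---------------------------------------------------------------------------
# CSV ingestion


def _parse_meta_lines(text: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            continue
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    return meta


def read_titration_csv(path, unit_config: str = "uM") -> TitrationSeries:
    """Read a titration series from CSV.

    Expected columns: ``conc_uM`` (or ``conc_<unit>``), ``F`` and optionally
    ``A_ex``, ``A_em``, ``temperature_K``. ``#``-prefixed header lines may
    carry ``temperature_K``, ``lambda_ex_nm``, ``lambda_em_nm`` and ``label``
    metadata. Concentrations are converted to mol·L⁻¹ on ingestion and rows
    sorted by concentration; exactly one zero-concentration row (the F₀
    reference) must be present for quenching analyses.
    """
    if unit_config not in CONC_UNIT_SCALES:
        raise AnalysisError(f"unknown concentration unit {unit_config!r}")
    scale = CONC_UNIT_SCALES[unit_config]

    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    meta = _parse_meta_lines(text)
    df = pd.read_csv(io.StringIO(text), comment="#", float_precision="round_trip")

    conc_col = f"conc_{unit_config}"
    if conc_col not in df.columns:
        # fall back to any conc_* column with a recognized unit suffix
        cands = [c for c in df.columns if c.startswith("conc_")]
        if not cands:
            raise AnalysisError("missing concentration column conc_uM")
        conc_col = cands[0]
        unit = conc_col.removeprefix("conc_")
        if unit not in CONC_UNIT_SCALES:
            raise AnalysisError(f"unknown concentration unit {unit!r}")
        scale = CONC_UNIT_SCALES[unit]
    if "F" not in df.columns:
        raise AnalysisError("missing intensity column F")

    if (df[conc_col] < 0).any() or (df["F"] < 0).any():
        raise AnalysisError("invalid measurement: negative value")

    concs = df[conc_col].to_numpy(dtype=float) * scale
    if len(np.unique(concs)) != len(concs):
        raise AnalysisError("ambiguous titration point: duplicate concentration")
    if not np.any(concs == 0.0):
        raise AnalysisError("no reference point: series lacks a [Q]=0 row")

    def _col(name):
        return df[name].to_numpy(dtype=float) if name in df.columns else None

    a_ex, a_em = _col("A_ex"), _col("A_em")
    points = [
        TitrationPoint(
            quencher_conc=float(c),
            f_obs=float(f),
            a_ex=None if a_ex is None else float(a_ex[i]),
            a_em=None if a_em is None else float(a_em[i]),
        )
        for i, (c, f) in enumerate(zip(concs, df["F"].to_numpy(dtype=float)))
    ]

    if "temperature_K" in meta:
        temperature = float(meta["temperature_K"])
    elif "temperature_K" in df.columns:
        tcol = df["temperature_K"].to_numpy(dtype=float)
        if len(np.unique(tcol)) != 1:
            raise AnalysisError("temperature_K column is not constant")
        temperature = float(tcol[0])
    else:
        temperature = 303.0

    return TitrationSeries(
        points=points,
        temperature=temperature,
        lambda_ex=float(meta.get("lambda_ex_nm", 279.0)),
        lambda_em=float(meta.get("lambda_em_nm", 341.0)),
        label=meta.get("label", ""),
    )


def write_titration_csv(series: TitrationSeries, path) -> None:
    """Write a series in the dialect :func:`read_titration_csv` accepts.

    Values are written at full ``repr`` precision so a read/write cycle
    round-trips numerically.
    """
    has_abs = all(p.has_absorbances for p in series.points)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# temperature_K: {series.temperature!r}\n")
        fh.write(f"# lambda_ex_nm: {series.lambda_ex!r}\n")
        fh.write(f"# lambda_em_nm: {series.lambda_em!r}\n")
        if series.label:
            fh.write(f"# label: {series.label}\n")
        cols = "conc_uM,F" + (",A_ex,A_em" if has_abs else "")
        fh.write(cols + "\n")
        for p in series.points:
            row = f"{p.quencher_conc / 1e-6!r},{p.f_obs!r}"
            if has_abs:
                row += f",{p.a_ex!r},{p.a_em!r}"
            fh.write(row + "\n")


def read_spectra_csv(path) -> list[Spectrum]:
    """Read a multi-column spectrum CSV: first column the axis, one intensity
    column per titration point. A ``# axis_kind:`` header line declares the
    axis type; intensity column headers are either ``conc_uM=<x>`` (parsed to
    mol·L⁻¹ in ``meta``) or free-text labels.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    meta = _parse_meta_lines(text)
    axis_kind = meta.get("axis_kind")
    if axis_kind is None:
        raise AnalysisError("spectrum CSV lacks '# axis_kind:' header")
    df = pd.read_csv(io.StringIO(text), comment="#", float_precision="round_trip")
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    out = []
    for col in df.columns[1:]:
        m: float | str = col
        if col.startswith("conc_uM="):
            m = float(col.removeprefix("conc_uM=")) * 1e-6
        out.append(Spectrum(axis_kind, axis, df[col].to_numpy(dtype=float), meta=m))
    return out


def write_spectra_csv(spectra: list[Spectrum], path) -> None:
    if not spectra:
        raise AnalysisError("no spectra to write")
    kinds = {s.axis_kind for s in spectra}
    if len(kinds) != 1:
        raise AnalysisError("incomparable spectra: mixed axis kinds")
    axis = spectra[0].axis
    cols = {}
    for i, s in enumerate(spectra):
        if isinstance(s.meta, float):
            name = f"conc_uM={s.meta / 1e-6:g}"
        else:
            name = str(s.meta) if s.meta is not None else f"spectrum_{i}"
        cols[name] = s.intensity
    df = pd.DataFrame({"axis": axis, **cols})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# axis_kind: {spectra[0].axis_kind}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Inner-filter correction


def correct_inner_filter(f_obs, a_ex, a_em):
    """Correct observed fluorescence for the inner filter effect.

    Absorption of excitation and emission light by the sample attenuates the
    measured signal; the standard (Lakowicz) correction restores it as

        F_corr = F_obs · 10^((A_ex + A_em) / 2)

    with decadic absorbances. The correction is the identity at zero
    absorbance, symmetric in the two absorbances, and never decreases the
    intensity. Accepts scalars or arrays.
    """
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise AnalysisError("invalid absorbance")
    out = np.asarray(f_obs, dtype=float) * 10.0 ** ((a_ex + a_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def correct_series(series: TitrationSeries, passthrough: bool = False) -> TitrationSeries:
    """Apply the inner-filter correction to every point of a series.

    Every point must carry both absorbances; the original intensity is kept
    in ``f_raw``. With ``passthrough=True`` points lacking absorbances are
    returned unchanged with a warning (for data acquired in a regime where
    the correction is negligible); mixing corrected and uncorrected points
    without the flag is rejected.
    """
    have = [p.has_absorbances for p in series.points]
    if not passthrough and any(have) and not all(have):
        raise AnalysisError("inconsistent absorbance columns")
    if not all(have):
        if not passthrough:
            raise AnalysisError("inconsistent absorbance columns")
        warnings.warn(
            "series lacks absorbance columns; returning intensities uncorrected",
            stacklevel=2,
        )

    new_points = []
    for p in series.points:
        if p.has_absorbances:
            f_corr = correct_inner_filter(p.f_obs, p.a_ex, p.a_em)
            new_points.append(replace(p, f_obs=f_corr, f_raw=p.f_obs))
        else:
            new_points.append(p)
    return TitrationSeries(
        points=new_points,
        temperature=series.temperature,
        lambda_ex=series.lambda_ex,
        lambda_em=series.lambda_em,
        label=series.label,
    )


# ---------------------------------------------------------------------------
# Peak utilities


def locate_peak(spectrum: Spectrum, window: tuple[float, float]) -> PeakResult:
    """Locate the band maximum inside ``window`` (axis units).

    The discrete maximum is refined by fitting a parabola through it and its
    two neighbours (sub-grid vertex); a maximum at a window edge is returned
    at the grid value. Ties between equal maxima break toward the lower axis
    value; a flat window returns its leftmost point flagged ``flat``.
    """
    lo, hi = min(window), max(window)
    axis, inten = spectrum.axis, spectrum.intensity
    if axis.size > 1 and axis[0] > axis[-1]:  # normalize to ascending
        axis, inten = axis[::-1], inten[::-1]
    sel = np.flatnonzero((axis >= lo) & (axis <= hi))
    if sel.size == 0:
        raise AnalysisError("window outside axis")
    if sel.size < 3:
        raise AnalysisError("window contains fewer than 3 grid points")
    x, y = axis[sel], inten[sel]
    step = float(np.median(np.diff(x)))

    if np.all(y == y[0]):
        return PeakResult(float(x[0]), float(y[0]), (lo, hi), spectrum.axis_kind, step, flat=True)

    i = int(np.argmax(y))  # argmax takes the first (lowest-axis) maximum
    if i == 0 or i == len(y) - 1:
        return PeakResult(float(x[i]), float(y[i]), (lo, hi), spectrum.axis_kind, step)

    # 3-point parabola through (x[i-1..i+1], y[i-1..i+1])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        pos, height = float(x[i]), float(y[i])
    else:
        delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
        delta = float(np.clip(delta, -1.0, 1.0))
        pos = float(x[i] + delta * step)
        height = float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta)
    pos = float(np.clip(pos, lo, hi))
    return PeakResult(pos, height, (lo, hi), spectrum.axis_kind, step)


def peak_shift(
    reference: PeakResult, treated: PeakResult, threshold: float | None = None
) -> ShiftRecord:
    """Signed peak displacement (treated − reference) with direction label.

    ``threshold`` defaults to half the reference grid step — shifts smaller
    than the grid resolution are reported as "none".
    """
    if reference.axis_kind != treated.axis_kind:
        raise AnalysisError("incomparable spectra: mismatched axis kinds")
    if threshold is None:
        threshold = reference.grid_step / 2.0
    shift = treated.position - reference.position
    if abs(shift) < threshold or shift == 0.0:
        direction = "none"
    elif reference.axis_kind in _NM_AXES:
        direction = "red" if shift > 0 else "blue"
    else:  # wavenumber axis: lower cm⁻¹ = lower energy = red
        direction = "red" if shift < 0 else "blue"
    return ShiftRecord(float(shift), direction, float(threshold), reference.axis_kind)
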