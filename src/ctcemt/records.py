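"""Core record types shared across the pipeline.

The measured object throughout is a single cell: a segmented region with one
Corrected Total Cell Fluorescence (CTCF) value per fluorescence channel,
``CTCF = IntegratedDensity - Area * MeanBackground``, and the derived
background-corrected mean intensity ``CTCF / Area``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

MARKERS = ("dapi", "keratin", "vimentin", "cd45")


class CtcemtError(Exception):
    """Base class for all package errors."""


class ConfigError(CtcemtError):
    """Invalid configuration or input contract violation."""


class GenerationError(CtcemtError):
    """Synthetic-data generation could not satisfy its constraints."""


@dataclass
class CellRecord:
    """One segmented cell with per-marker CTCF measurements.

    ``mean_intensity[m] == ctcf[m] / area`` holds exactly for every marker;
    negative CTCF (cell dimmer than the local background) is preserved.
    A cell is a CTC iff it is DAPI-positive and CD45-negative; keratin is a
    measurement, never a gate, so keratin-negative CTCs are representable.
    """

    cell_id: str
    sample_id: str
    area: float
    ctcf: dict[str, float] = field(default_factory=dict)
    is_dapi_positive: bool | None = None
    is_cd45_negative: bool | None = None

    @property
    def mean_intensity(self) -> dict[str, float]:
        return {m: v / self.area for m, v in self.ctcf.items()}

    @property
    def is_ctc(self) -> bool | None:
        if self.is_dapi_positive is None or self.is_cd45_negative is None:
            return None
        return self.is_dapi_positive and self.is_cd45_negative


@dataclass(frozen=True)
class CellLineProfile:
    """Distributional parameters of one reference cell line.

    Marginal means/SDs are background-corrected mean intensities (CTCF/area);
    ``ratio_range`` bounds the per-cell vimentin/keratin ratio and, when set,
    is enforced by rejection sampling in the generator. ``marker_correlation``
    is the Gaussian-copula correlation between the two markers within a cell.
    """

    name: str
    keratin_mean: float
    keratin_sd: float
    vimentin_mean: float
    vimentin_sd: float
    ratio_range: tuple[float, float] | None = None
    marker_correlation: float = -0.3

    def __post_init__(self) -> None:
        if self.keratin_mean < 0 or self.vimentin_mean < 0:
            raise ConfigError(f"{self.name}: marker means must be >= 0")
        if self.keratin_sd < 0 or self.vimentin_sd < 0:
            raise ConfigError(f"{self.name}: marker SDs must be >= 0")
        if not -1.0 <= self.marker_correlation <= 1.0:
            raise ConfigError(f"{self.name}: correlation must be in [-1, 1]")
        if self.ratio_range is not None and self.ratio_range[0] > self.ratio_range[1]:
            raise ConfigError(f"{self.name}: ratio_range min > max")


def _lognormal_sigma2(mean: float, sd: float) -> float:
    return math.log1p((sd / mean) ** 2)


def copula_correlation_from_ratio_sd(
    keratin_mean: float,
    keratin_sd: float,
    vimentin_mean: float,
    vimentin_sd: float,
    ratio_mean: float,
    ratio_sd: float,
) -> float:
    """Copula correlation that reproduces an observed vim/K ratio SD.

    Under lognormal marginals with a Gaussian copula the log-ratio variance is
    ``s_v^2 + s_K^2 - 2 rho s_v s_K``; solving for ``rho`` moment-matches the
    generator to a reported ratio dispersion instead of asserting a
    correlation the source data do not print. Result clipped to [-1, 1].
    """
    s2_k = _lognormal_sigma2(keratin_mean, keratin_sd)
    s2_v = _lognormal_sigma2(vimentin_mean, vimentin_sd)
    s2_r = _lognormal_sigma2(ratio_mean, ratio_sd)
    denom = 2.0 * math.sqrt(s2_k * s2_v)
    if denom == 0.0:
        return 0.0
    return max(-1.0, min(1.0, (s2_v + s2_k - s2_r) / denom))


def _reference(name, km, ks, vm, vs, rlo, rhi, rm, rs) -> CellLineProfile:
    rho = copula_correlation_from_ratio_sd(km, ks, vm, vs, rm, rs)
    return CellLineProfile(
        name=name,
        keratin_mean=km,
        keratin_sd=ks,
        vimentin_mean=vm,
        vimentin_sd=vs,
        ratio_range=(rlo, rhi),
        marker_correlation=rho,
    )


#: Reference breast-cancer cell-line profiles (CTCF/area units) measured on
#: cytospins: luminal/"epithelial" MCF-7 and T47D, basal/"mesenchymal"
#: MDA.MB231 and Hs578T, and MCF-7 after EGF-induced EMT. The copula
#: correlation of each profile is moment-matched to the line's reported vim/K
#: ratio SD (see :func:`copula_correlation_from_ratio_sd`).
REFERENCE_PROFILES: dict[str, CellLineProfile] = {
    p.name: p
    for p in (
        _reference("MCF-7", 87.34, 18.99, 15.68, 2.58, 0.12, 0.49, 0.19, 0.05),
        _reference("T47D", 35.43, 10.62, 6.73, 2.16, 0.17, 0.43, 0.19, 0.07),
        _reference("MDA.MB231", 11.47, 4.87, 43.38, 12.06, 1.19, 10.88, 4.44, 1.98),
        _reference("Hs578T", 4.02, 1.00, 53.64, 24.81, 5.47, 38.88, 13.14, 5.08),
        _reference("MCF-7-EGF", 18.37, 7.56, 23.63, 9.10, 0.45, 5.05, 1.57, 1.02),
        # pooled patient CTCs: heterogeneous, spanning the whole EMT scale
        _reference("CTC", 30.06, 25.00, 26.42, 25.45, 0.0, 22.46, 1.62, 3.96),
    )
}


@dataclass
class PatientRecord:
    """One metastatic breast-cancer patient with CellSearch CTC keratin data.

    Inclusion requires at least 2 CTCs. ``triple_negative`` implies ER, PR and
    HER2 all negative. Survival is overall survival from treatment initiation;
    ``os_event`` is True when death was observed (False = censored).
    """

    patient_id: str
    ctc_keratin_values: list[float]
    er_status: str = "unknown"
    pr_status: str = "unknown"
    her2_status: str = "unknown"
    triple_negative: bool = False
    os_months: float = 0.0
    os_event: bool = False
    keratin_group: str | None = None  # "HK" / "LK", set by label_patients
    fraction_high: float | None = None

    def __post_init__(self) -> None:
        if len(self.ctc_keratin_values) < 2:
            raise ConfigError(
                f"patient {self.patient_id}: needs >=2 CTC keratin values"
            )
        if self.os_months < 0:
            raise ConfigError(f"patient {self.patient_id}: negative os_months")
        if self.triple_negative and not all(
            s == "negative" for s in (self.er_status, self.pr_status, self.her2_status)
        ):
            raise ConfigError(
                f"patient {self.patient_id}: triple_negative requires "
                "ER/PR/HER2 all negative"
            )
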