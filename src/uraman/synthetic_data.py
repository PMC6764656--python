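"""Seeded synthetic urine Raman cohorts.

Emulates the statistical structure the analysis pipeline assumes: each
donor has a metabolite concentration profile (urea dominating the 1002
cm^-1 band, plus creatinine 680, collagen 870, uric acid 981 and glucose
1071/1117 cm^-1), modulated multiplicatively by sex, birth year, a
donor-level lognormal factor and a day-level (specimen) lognormal
factor; each peak is a Lorentzian on the working grid; every spectrum
rides on a polynomial baseline plus an exponentially decaying
fluorescence background; each replicate scan adds independent Gaussian
noise. A fixed-profile control emulates a commercial synthetic-urine
negative standard.

Random streams are split deterministically by (donor, specimen, scan)
with :class:`numpy.random.SeedSequence`, so generating a subset of the
cohort never shifts the draws of the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .errors import ConfigError
from .spectra_io import (
    DEFAULT_GRID,
    METADATA_COLUMNS,
    RamanSpectrum,
    validate_metadata,
)


@dataclass(frozen=True)
class PeakSpec:
    """One Raman band: Lorentzian center/width/height plus a metabolite tag."""

    center: float
    fwhm: float
    base_amplitude: float
    metabolite: str

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ConfigError(f"peak {self.metabolite!r}: fwhm must be > 0")
        if self.base_amplitude < 0:
            raise ConfigError(
                f"peak {self.metabolite!r}: base_amplitude must be >= 0"
            )


def default_peaks() -> list[PeakSpec]:
    """The named urine bands. Relative amplitudes are order-of-magnitude
    choices (urea dominant); absolute units are arbitrary detector counts."""
    return [
        PeakSpec(1002.0, 10.0, 1.00, "urea"),
        PeakSpec(981.0, 10.0, 0.30, "uric_acid"),
        PeakSpec(680.0, 10.0, 0.45, "creatinine"),
        PeakSpec(870.0, 10.0, 0.20, "collagen"),
        PeakSpec(1071.0, 10.0, 0.18, "glucose"),
        PeakSpec(1117.0, 10.0, 0.15, "glucose"),
    ]


#: Band switched on by the menstruation flag (heme/blood marker region).
BLOOD_PEAK = PeakSpec(1545.0, 12.0, 1.0, "blood")


@dataclass
class CohortConfig:
    """Generator settings. Defaults mirror the cross-sectional study
    shape: 39 female and 9 male donors, ~5 specimens each, 10 replicate
    scans per specimen, donors mostly born 1995-1998 (a young cohort)
    with a tail across the full range."""

    n_female: int = 39
    n_male: int = 9
    specimens_per_donor: int = 5
    scans_per_specimen: int = 10
    birth_year_range: tuple[int, int] = (1947, 2000)
    peaks: list[PeakSpec] = field(default_factory=default_peaks)
    sex_multiplier: dict[str, float] = field(default_factory=dict)
    age_slope: dict[str, float] = field(default_factory=dict)
    donor_cv: float = 0.15
    day_cv: float = 0.08
    menstruation_effect: float = 0.0
    baseline_coeffs: tuple[float, ...] = (0.5, -2.0e-4, 5.0e-8)
    fluorescence_amp: float = 1.0
    fluorescence_decay: float = 800.0
    noise_sd: float = 0.01
    peak_shape: str = "lorentzian"
    control_scale: float = 0.5
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_female", "n_male", "specimens_per_donor", "scans_per_specimen"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.donor_cv < 0 or self.day_cv < 0 or self.noise_sd < 0:
            raise ConfigError("donor_cv, day_cv and noise_sd must be >= 0")
        if self.peak_shape not in ("lorentzian", "gaussian"):
            raise ConfigError(f"unknown peak_shape {self.peak_shape!r}")
        self.grid = np.asarray(self.grid, dtype=float)
        lo, hi = self.grid[0], self.grid[-1]
        for p in self.peaks:
            if not lo <= p.center <= hi:
                raise ConfigError(
                    f"peak {p.metabolite!r} center {p.center} outside grid "
                    f"[{lo}, {hi}]"
                )


def _profile(grid: np.ndarray, peak: PeakSpec, shape: str) -> np.ndarray:
    """Unit-height band profile of one peak on the grid."""
    if shape == "lorentzian":
        gamma = peak.fwhm / 2.0
        return gamma**2 / ((grid - peak.center) ** 2 + gamma**2)
    return np.exp(-4.0 * np.log(2.0) * (grid - peak.center) ** 2 / peak.fwhm**2)


def _background(config: CohortConfig) -> np.ndarray:
    x = config.grid
    poly = np.polynomial.polynomial.polyval(x, config.baseline_coeffs)
    fluor = config.fluorescence_amp * np.exp(-x / config.fluorescence_decay)
    return poly + fluor


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal draw with the given coefficient of variation."""
    if cv == 0.0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def _rng(config: CohortConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *key]))


_DONOR_STREAM, _SPECIMEN_STREAM, _SCAN_STREAM, _CONTROL_STREAM = 1, 2, 3, 4


def _donor_draws(config: CohortConfig, donor_idx: int, is_male: bool):
    """Birth year and per-peak donor amplitudes for one donor."""
    rng = _rng(config, _DONOR_STREAM, donor_idx)
    lo, hi = config.birth_year_range
    # 87.5% of specimens in the study came from donors aged 19-22
    if rng.random() < 0.875:
        birth_year = int(rng.integers(max(lo, 1995), min(hi, 1998) + 1))
    else:
        birth_year = int(rng.integers(lo, hi + 1))
    median_year = 1996
    amps = []
    for p_idx, peak in enumerate(config.peaks):
        amp = peak.base_amplitude
        if is_male:
            amp *= config.sex_multiplier.get(peak.metabolite, 1.0)
        slope = config.age_slope.get(peak.metabolite, 0.0)
        amp *= max(0.0, 1.0 + slope * (birth_year - median_year))
        amp *= _lognormal_factor(
            np.random.default_rng(
                np.random.SeedSequence(
                    [int(config.seed), _DONOR_STREAM, donor_idx, 100 + p_idx]
                )
            ),
            config.donor_cv,
        )
        amps.append(amp)
    return birth_year, np.asarray(amps)


def _specimen_scans(
    config: CohortConfig,
    donor_idx: int,
    specimen_idx: int,
    donor_amps: np.ndarray,
    specimen_id: str,
    extra_peaks: list[tuple[PeakSpec, float]] | None = None,
) -> list[RamanSpectrum]:
    rng_spec = _rng(config, _SPECIMEN_STREAM, donor_idx, specimen_idx)
    day = _lognormal_factor(rng_spec, config.day_cv, size=donor_amps.size)
    amps = donor_amps * day
    clean = _background(config)
    for amp, peak in zip(amps, config.peaks):
        clean = clean + amp * _profile(config.grid, peak, config.peak_shape)
    for peak, amp in extra_peaks or []:
        clean = clean + amp * _profile(config.grid, peak, config.peak_shape)
    scans = []
    for k in range(config.scans_per_specimen):
        rng_scan = _rng(config, _SCAN_STREAM, donor_idx, specimen_idx, k)
        noisy = clean + rng_scan.normal(0.0, config.noise_sd, clean.size)
        scans.append(
            RamanSpectrum(
                shifts=config.grid,
                intensities=noisy,
                specimen_id=specimen_id,
                scan_index=k + 1,
            )
        )
    return scans


def _meta_row(specimen_id, donor_id, sex, birth_year, when, menstruation=False,
              is_control=False) -> dict:
    return {
        "specimen_id": specimen_id,
        "donor_id": donor_id,
        "sex": sex,
        "birth_year": birth_year,
        "collection_date": when.isoformat(),
        "menstruation": menstruation,
        "is_control": is_control,
    }


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[RamanSpectrum], pd.DataFrame]:
    """Cross-sectional cohort: every donor contributes
    ``specimens_per_donor`` specimens of ``scans_per_specimen`` scans."""
    scans: list[RamanSpectrum] = []
    rows: list[dict] = []
    start = date(2017, 1, 8)
    n_donors = config.n_female + config.n_male
    for d in range(n_donors):
        is_male = d >= config.n_female
        sex = "M" if is_male else "F"
        donor_id = f"D{d:03d}"
        birth_year, donor_amps = _donor_draws(config, d, is_male)
        for s in range(config.specimens_per_donor):
            sid = f"{donor_id}S{s:02d}"
            scans.extend(
                _specimen_scans(config, d, s, donor_amps, sid)
            )
            rows.append(
                _meta_row(
                    sid, donor_id, sex, birth_year,
                    start + timedelta(days=7 * s + d),
                )
            )
    meta = validate_metadata(pd.DataFrame(rows, columns=list(METADATA_COLUMNS)))
    return scans, meta


def generate_control(
    config: CohortConfig, n_scans: int = 10
) -> tuple[list[RamanSpectrum], pd.DataFrame]:
    """Scans of the fixed synthetic-urine control standard.

    The control's amplitude profile is the base peak table scaled by
    ``control_scale`` (a negative-control standard is more dilute than
    urine), with no donor or day variation; baseline and noise models
    are shared with the cohort.
    """
    clean = _background(config)
    for peak in config.peaks:
        clean = clean + (
            config.control_scale * peak.base_amplitude
        ) * _profile(config.grid, peak, config.peak_shape)
    scans = []
    for k in range(int(n_scans)):
        rng = _rng(config, _CONTROL_STREAM, k)
        noisy = clean + rng.normal(0.0, config.noise_sd, clean.size)
        scans.append(
            RamanSpectrum(
                shifts=config.grid,
                intensities=noisy,
                specimen_id="CTRL",
                scan_index=k + 1,
            )
        )
    meta = validate_metadata(
        pd.DataFrame(
            [_meta_row("CTRL", "CTRL", "F", 2000, date(2017, 1, 8),
                       is_control=True)],
            columns=list(METADATA_COLUMNS),
        )
    )
    return scans, meta


def generate_30day(
    config: CohortConfig,
    n_female: int = 3,
    n_male: int = 1,
    days: int = 30,
    menstruation_days: dict[str, set[int]] | None = None,
) -> tuple[list[RamanSpectrum], pd.DataFrame]:
    """Longitudinal mode: each donor contributes one first-morning-void
    specimen per day for ``days`` days.

    ``menstruation_days`` maps donor_id -> 1-based day numbers; when
    omitted, each female donor is assigned a 5-day window at a
    donor-stream-drawn start day. The menstruation effect (an additive
    blood-marker band at 1545 cm^-1) defaults to amplitude 0, so default
    syntheses carry a flag with no spectral consequence.
    """
    n_donors = n_female + n_male
    donor_ids = [f"F{i + 1}" for i in range(n_female)] + [
        f"M{i + 1}" for i in range(n_male)
    ]
    if menstruation_days is None:
        menstruation_days = {}
        for d in range(n_female):
            rng = _rng(config, _DONOR_STREAM, d, 999)
            first = int(rng.integers(1, max(2, days - 4)))
            menstruation_days[donor_ids[d]] = set(range(first, first + 5))
    for donor_id, dayset in menstruation_days.items():
        if donor_id not in donor_ids:
            raise ConfigError(f"unknown donor {donor_id!r} in menstruation_days")
        if donor_ids.index(donor_id) >= n_female:
            raise ConfigError(
                f"menstruation days listed for male donor {donor_id!r}"
            )
        if any(not 1 <= d <= days for d in dayset):
            raise ConfigError(f"menstruation day out of 1..{days} for {donor_id!r}")
    scans: list[RamanSpectrum] = []
    rows: list[dict] = []
    start = date(2018, 3, 1)
    for d in range(n_donors):
        donor_id = donor_ids[d]
        is_male = d >= n_female
        sex = "M" if is_male else "F"
        birth_year, donor_amps = _donor_draws(config, d, is_male)
        for day_num in range(1, days + 1):
            sid = f"{donor_id}D{day_num:02d}"
            flagged = day_num in menstruation_days.get(donor_id, set())
            extra = (
                [(BLOOD_PEAK, config.menstruation_effect)]
                if flagged and config.menstruation_effect != 0.0
                else None
            )
            scans.extend(
                _specimen_scans(config, d, day_num, donor_amps, sid, extra)
            )
            rows.append(
                _meta_row(
                    sid, donor_id, sex, birth_year,
                    start + timedelta(days=day_num - 1),
                    menstruation=flagged,
                )
            )
    meta = validate_metadata(pd.DataFrame(rows, columns=list(METADATA_COLUMNS)))
    return scans, meta
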