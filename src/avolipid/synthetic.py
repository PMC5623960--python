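"""Synthetic lipidome and LC-MS acquisition generator.

Produces ground-truth tissue lipid profiles (mesocarp, idioblast-enriched
fraction, seed), positive-mode ESI-TOF style centroided scan maps with
adduct/isotopologue structure, drifting background channels and noise, and
UV peak-area tables for the targeted quantification layer. Every synthetic
peak is recorded in a ground-truth ledger so downstream stages can be
checked against an oracle.

Chromatographic background is modeled as dedicated, slowly drifting m/z
channels rather than an offset under analyte peaks, so that windowed
quantile baseline correction removes it without biasing analyte areas.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import chem

# --- stages and tissues -------------------------------------------------

TISSUES = ("mesocarp", "idioblast", "seed")
GROWTH_STAGES = (45, 60, 90, 120, 150, 180, 210, 240, 270, 300)
RIPENING_STAGES = ("unripe", "breaker", "ripe")

_RIPENING_CODE = {"unripe": 1001, "breaker": 1002, "ripe": 1003}
_TISSUE_CODE = {t: i for i, t in enumerate(TISSUES)}

#: reported acetogenin analytes; Persin and Persenone B co-elute and are
#: modeled as a single merged analyte throughout
ACETOGENIN_ANALYTES = (
    "Persenone A",
    "Persin/Persenone B",
    "Persenone C",
    "AcO-avocadene",
    "AcO-avocadenyne",
    "UPA",
)

#: default acetogenin pool shares (sum to 1 per tissue state)
MESOCARP_SHARES = {
    "Persenone A": 0.527,
    "Persin/Persenone B": 0.258,
    "AcO-avocadene": 0.120,
    "Persenone C": 0.050,
    "AcO-avocadenyne": 0.025,
    "UPA": 0.020,
}
SEED_YOUNG_SHARES = {
    "AcO-avocadene": 0.537,
    "AcO-avocadenyne": 0.0785,
    "UPA": 0.146,
    "Persin/Persenone B": 0.0451,
    "Persenone A": 0.140,
    "Persenone C": 0.0534,
}
SEED_MATURE_SHARES = {
    "AcO-avocadene": 0.363,
    "AcO-avocadenyne": 0.0499,
    "UPA": 0.0554,
    "Persin/Persenone B": 0.174,
    "Persenone A": 0.250,
    "Persenone C": 0.1077,
}

MESOCARP_TAC_FW = 3.0  # mg/gFW, stage-invariant
#: idioblast-fraction TAC as a fraction of whole-mesocarp TAC
IDIOBLAST_TAC_RATIO = {"growth": 0.85, "unripe": 0.80, "breaker": 0.90, "ripe": 0.981}
IDIOBLAST_RATIO_CV = 0.008

SEED_POWER_A = 32.7
SEED_POWER_B = 2.246
SEED_TAC_FOLD = 4.5  # mean TAC(-DW) of seeds from fruits >90 g vs <=90 g

_MESOCARP_DW = dict(zip(GROWTH_STAGES, np.linspace(0.13, 0.30, len(GROWTH_STAGES))))
SEED_DW_FRACTION = dict(zip(GROWTH_STAGES, np.linspace(0.15, 0.42, len(GROWTH_STAGES))))


def _seed_tac_dw_table() -> dict[int, float]:
    """Per-stage seed TAC in mg/gDW.

    Shapes follow the power-law curve on dry-weight fraction; the >90 g
    group is rescaled so the mean fold-increase over the <=90 g group hits
    the configured default exactly at zero noise.
    """
    base = {s: SEED_POWER_A * SEED_DW_FRACTION[s] ** SEED_POWER_B for s in GROWTH_STAGES}
    small = [base[s] for s in GROWTH_STAGES if s <= 90]
    big = [base[s] for s in GROWTH_STAGES if s > 90]
    scale = SEED_TAC_FOLD * np.mean(small) / np.mean(big)
    return {s: (v * scale if s > 90 else v) for s, v in base.items()}


SEED_TAC_DW = _seed_tac_dw_table()

#: glycerolipid / phospholipid background analytes: (name, mesocarp growth,
#: mesocarp ripe delta fraction, seed young, seed mature fraction)
_GLYCEROLIPIDS = {
    "TAG 50:1": (12.0, -0.40, 5.0, 0.25),
    "TAG 52:2": (15.0, -0.40, 6.0, 0.20),
    "TAG 54:3": (10.0, -0.45, 4.0, 0.20),
    "DAG 36:2": (3.0, +0.50, 2.0, 0.40),
    "DAG 36:4": (2.0, +0.40, 1.5, 0.40),
    "DAG 39:5": (0.8, -0.50, 0.6, 0.50),
    "MAG 18:1": (0.5, 0.0, 0.4, 0.60),
    "PC 34:2": (1.0, -0.20, 0.8, 0.50),
    "PE 36:2": (0.8, -0.20, 0.6, 0.50),
    # sterol background compound; its m/z region carries the ambiguous
    # multi-candidate annotation cluster
    "Cholestadienol isomer 1": (0.5, 0.0, 0.3, 1.0),
}


# --- domain types -------------------------------------------------------


@dataclass(frozen=True)
class LipidRecord:
    """One reference lipid entry with its hierarchical classification."""

    record_id: str
    name: str
    formula: dict[str, int]
    monoisotopic_mass: float
    category: str
    main_class: str
    subclass: str = ""
    rt_affinity: float = 10.0  # nominal elution center, minutes

    def __post_init__(self):
        computed = chem.monoisotopic_mass(self.formula)
        if abs(computed - self.monoisotopic_mass) > 1e-4:
            raise ValueError(
                f"{self.record_id}: stated mass {self.monoisotopic_mass} differs "
                f"from formula mass {computed:.5f}"
            )
        if self.main_class and not self.main_class.startswith(self.category):
            raise ValueError(f"{self.record_id}: main_class must extend category code")
        if self.subclass and not self.subclass.startswith(self.main_class):
            raise ValueError(f"{self.record_id}: subclass must extend main_class code")

    @property
    def formula_string(self) -> str:
        return chem.formula_to_string(self.formula)

    def class_at_level(self, level: int) -> str:
        if level == 1:
            return self.category
        if level == 2:
            return self.main_class
        if level == 3:
            return self.subclass or self.main_class
        raise ValueError(f"unknown hierarchy level {level}")


@dataclass(frozen=True)
class TissueProfile:
    """Ground-truth analyte concentrations for one biological sample."""

    tissue: str
    stage: int | str
    fresh_weight: float  # g, whole fruit
    dw_fraction: float
    concentrations: dict[str, float]  # analyte -> mg per g FW
    replicate: int = 0

    def __post_init__(self):
        if not 0.0 < self.dw_fraction < 1.0:
            raise ValueError(f"dw_fraction must be in (0,1), got {self.dw_fraction}")
        if any(v < 0 for v in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")

    @property
    def sample_id(self) -> str:
        return f"{self.tissue}_{self.stage}_r{self.replicate}"

    @property
    def tac(self) -> float:
        """Total acetogenin concentration, mg/gFW."""
        return sum(self.concentrations.get(a, 0.0) for a in ACETOGENIN_ANALYTES)

    def acetogenin_shares(self) -> dict[str, float]:
        tac = self.tac
        if tac <= 0:
            raise ValueError("TAC is zero; shares undefined")
        return {
            a: self.concentrations.get(a, 0.0) / tac for a in ACETOGENIN_ANALYTES
        }


@dataclass(frozen=True)
class AcquisitionSettings:
    """ESI-TOF positive-mode acquisition emulation parameters."""

    mz_min: float = 150.0
    mz_max: float = 1500.0
    scan_rate: float = 0.94  # scans per second
    gradient_length: float = 65.0  # minutes
    noise_sd: float = 0.0  # additive counts noise per centroid
    baseline_amplitude: float = 0.0  # drifting background channel level

    def __post_init__(self):
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be below mz_max")
        if self.scan_rate <= 0:
            raise ValueError("scan_rate must be positive")

    @property
    def n_scans(self) -> int:
        return int(self.gradient_length * 60.0 * self.scan_rate)

    def scan_times(self) -> np.ndarray:
        """Scan midpoint times in minutes, strictly increasing."""
        return (np.arange(self.n_scans) + 0.5) / self.scan_rate / 60.0


@dataclass
class ScanMap:
    """Time-ordered centroided spectra of one LC-MS run."""

    scan_times: np.ndarray  # minutes
    scans: list[tuple[np.ndarray, np.ndarray]]  # per scan: (mz, intensity)
    sample_id: str = ""

    def __post_init__(self):
        if len(self.scan_times) != len(self.scans):
            raise ValueError("scan_times and scans length mismatch")
        if np.any(np.diff(self.scan_times) <= 0):
            raise ValueError("scan_times must be strictly increasing")

    @property
    def n_scans(self) -> int:
        return len(self.scan_times)

    def total_ion_current(self) -> np.ndarray:
        return np.array([inten.sum() if inten.size else 0.0 for _, inten in self.scans])

    def copy(self) -> "ScanMap":
        return ScanMap(
            self.scan_times.copy(),
            [(mz.copy(), inten.copy()) for mz, inten in self.scans],
            self.sample_id,
        )


@dataclass(frozen=True)
class LedgerPeak:
    """One injected chromatographic peak (monoisotopic trace of one adduct)."""

    sample_id: str
    analyte: str
    adduct: str
    charge: int
    mz: float
    rt_center: float  # minutes
    fwhm_s: float
    apex_intensity: float
    isotope_abundances: tuple[float, ...]
    dropped: bool = False

    @property
    def sigma_s(self) -> float:
        return self.fwhm_s / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    @property
    def area(self) -> float:
        """Closed-form Gaussian area in counts*s."""
        return self.apex_intensity * self.sigma_s * math.sqrt(2.0 * math.pi)


@dataclass
class GroundTruthLedger:
    """Record of every synthesized peak plus skipped/dropped bookkeeping."""

    peaks: list[LedgerPeak] = field(default_factory=list)
    skipped: list[tuple[str, str, str, float]] = field(default_factory=list)

    def injected(self) -> list[LedgerPeak]:
        return [p for p in self.peaks if not p.dropped]

    def for_analyte(self, analyte: str) -> list[LedgerPeak]:
        return [p for p in self.peaks if p.analyte == analyte]


# --- lipid reference database -------------------------------------------

_CLUSTER_RT = 23.0


def _core_records() -> list[LipidRecord]:
    recs: list[LipidRecord] = []

    def add(rid, name, formula, cat, main, sub, rt):
        recs.append(
            LipidRecord(
                record_id=rid,
                name=name,
                formula=chem.parse_formula(formula),
                monoisotopic_mass=chem.monoisotopic_mass(formula),
                category=cat,
                main_class=main,
                subclass=sub,
                rt_affinity=rt,
            )
        )

    # mandatory 12-record sterol cluster: one C25H40O bile-acid-like entry
    # and eleven C27H42O entries split 3 secosteroids / 8 sterols
    add("LM0001", "Norchol-enal BA-1", "C25H40O", "ST", "ST04", "ST0401", _CLUSTER_RT)
    for i in range(3):
        add(
            f"LM{2 + i:04d}", f"Secosteroid SE-{i + 1}", "C27H42O",
            "ST", "ST03", "ST0301", _CLUSTER_RT + 0.1 * i,
        )
    for i in range(8):
        add(
            f"LM{5 + i:04d}", f"Cholestadienol isomer {i + 1}", "C27H42O",
            "ST", "ST01", "ST0101", _CLUSTER_RT + 0.05 * i,
        )

    # acetogenins (fatty acyls, odd carbon count, O >= 4)
    acet = [
        ("Persenone A", "C23H38O4", 15.0),
        ("Persin/Persenone B", "C23H40O4", 13.0),
        ("Persenone C", "C21H34O4", 17.0),
        ("AcO-avocadene", "C19H36O4", 9.0),
        ("AcO-avocadenyne", "C19H32O4", 10.5),
        ("UPA", "C21H38O4", 12.0),
    ]
    for i, (name, formula, rt) in enumerate(acet):
        add(f"LM{13 + i:04d}", name, formula, "FA", "FA07", "FA0705", rt)

    gly = [
        ("MAG 18:1", "C21H40O4", "GL", "GL01", "GL0101", 26.0),
        ("DAG 36:2", "C39H72O5", "GL", "GL02", "GL0201", 32.0),
        ("DAG 36:4", "C39H68O5", "GL", "GL02", "GL0201", 30.0),
        ("DAG 39:5", "C42H72O5", "GL", "GL02", "GL0201", 34.0),
        ("TAG 50:1", "C53H100O6", "GL", "GL03", "GL0301", 50.0),
        ("TAG 52:2", "C55H102O6", "GL", "GL03", "GL0301", 52.0),
        ("TAG 54:3", "C57H104O6", "GL", "GL03", "GL0301", 54.0),
        ("PC 34:2", "C42H80NO8P", "GP", "GP01", "GP0101", 28.0),
        ("PE 36:2", "C41H78NO8P", "GP", "GP02", "GP0201", 27.0),
    ]
    for i, (name, formula, cat, main, sub, rt) in enumerate(gly):
        add(f"LM{19 + i:04d}", name, formula, cat, main, sub, rt)
    return recs


def generate_lipid_db(seed: int, n_records: int = 32) -> list[LipidRecord]:
    """Generate the local lipid reference fixture.

    Always contains the 12-record sterol cluster (class counts ST04:1,
    ST03:3, ST01:8); at the default size it spans the FA, GL, GP and ST
    categories including the quantified acetogenins and TAG/DAG/MAG
    entries. Additional records beyond the core set are random
    glycerolipid species.
    """
    if n_records < 12:
        raise ValueError(
            f"n_records={n_records} cannot accommodate the mandatory "
            "12-record sterol fixture cluster"
        )
    core = _core_records()
    records = core[:n_records]
    rng = np.random.default_rng([int(seed), 7001])
    i = 0
    seen_names = {r.name for r in records}
    while len(records) < n_records:
        n_carbon = int(rng.integers(44, 61))
        n_db = int(rng.integers(0, 7))
        name = f"TAG {n_carbon}:{n_db}"
        if name in seen_names:
            name = f"TAG {n_carbon}:{n_db} iso{i}"
        formula = {"C": n_carbon + 3, "H": 2 * (n_carbon + 3) - 4 - 2 * n_db, "O": 6}
        records.append(
            LipidRecord(
                record_id=f"LMX{i:04d}",
                name=name,
                formula=formula,
                monoisotopic_mass=chem.monoisotopic_mass(formula),
                category="GL",
                main_class="GL03",
                subclass="GL0301",
                rt_affinity=float(45.0 + rng.uniform(0, 15)),
            )
        )
        seen_names.add(name)
        i += 1
    return records


def db_by_name(db: list[LipidRecord]) -> dict[str, LipidRecord]:
    return {r.name: r for r in db}


# --- tissue profiles ----------------------------------------------------


def _stage_code(stage: int | str) -> int:
    if isinstance(stage, str) and stage in _RIPENING_CODE:
        return _RIPENING_CODE[stage]
    try:
        grams = int(stage)
    except (TypeError, ValueError):
        raise ValueError(f"unknown stage {stage!r}") from None
    if grams not in GROWTH_STAGES:
        raise ValueError(f"unknown growth stage {stage!r}; valid: {GROWTH_STAGES}")
    return grams


def _is_ripening(stage: int | str) -> bool:
    return isinstance(stage, str) and stage in _RIPENING_CODE


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-preserving multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _base_state(tissue: str, stage: int | str):
    """Noise-free (TAC mg/gFW, shares, dw_fraction, fresh_weight, glycerolipids)."""
    ripening = _is_ripening(stage)
    grams = 300 if ripening else _stage_code(stage)
    progress = GROWTH_STAGES.index(grams) / (len(GROWTH_STAGES) - 1)
    rp = {"unripe": 0.0, "breaker": 0.5, "ripe": 1.0}[stage] if ripening else 0.0

    if tissue in ("mesocarp", "idioblast"):
        dw = 0.30 if ripening else _MESOCARP_DW[grams]
        shares = dict(MESOCARP_SHARES)
        tac = MESOCARP_TAC_FW
        if tissue == "idioblast":
            key = stage if ripening else "growth"
            tac *= IDIOBLAST_TAC_RATIO[key]
        gl_scale = 0.04 if tissue == "idioblast" else 1.0
        glycer = {}
        for name, (meso, ripe_delta, _seed_y, _seed_m) in _GLYCEROLIPIDS.items():
            c = meso * (1.0 + ripe_delta * rp)
            if tissue == "idioblast" and name == "DAG 39:5":
                c = meso * (1.0 + 1.5 * rp)  # odd-chain DAGs rise in idioblasts
            glycer[name] = max(c, 0.0) * gl_scale
    elif tissue == "seed":
        dw = 0.42 if ripening else SEED_DW_FRACTION[grams]
        shares = dict(SEED_MATURE_SHARES if (ripening or grams > 90) else SEED_YOUNG_SHARES)
        tac = SEED_TAC_DW[grams] * dw
        glycer = {
            name: seed_y * ((1 - progress) + seed_m * progress)
            for name, (_m, _d, seed_y, seed_m) in _GLYCEROLIPIDS.items()
        }
    else:
        raise ValueError(f"unknown tissue {tissue!r}; valid: {TISSUES}")
    return tac, shares, dw, float(grams), glycer


def generate_sample_profile(
    tissue: str,
    stage: int | str,
    seed: int,
    replicate: int = 0,
    noise_cv: float = 0.08,
    share_cv: float = 0.05,
) -> TissueProfile:
    """Draw one replicate tissue profile around the configured stage means.

    Replicate-level TAC noise is seeded by (seed, stage, replicate) only,
    so mesocarp and idioblast profiles drawn with the same arguments are
    paired the way tissue fractions from one fruit are; the
    idioblast/mesocarp TAC ratio then varies only by a small ratio noise.
    With both CVs at zero the profile equals the configured means exactly.
    """
    code = _stage_code(stage) if not _is_ripening(stage) else _RIPENING_CODE[stage]
    tac, shares, dw, fw, glycer = _base_state(tissue, stage)

    rng_tac = np.random.default_rng([int(seed), int(replicate), code, 101])
    tac *= float(_lognormal_factor(rng_tac, noise_cv))
    if tissue == "idioblast" and noise_cv > 0:
        rng_ratio = np.random.default_rng([int(seed), int(replicate), code, 103])
        tac *= float(_lognormal_factor(rng_ratio, IDIOBLAST_RATIO_CV))

    rng_shares = np.random.default_rng(
        [int(seed), int(replicate), code, _TISSUE_CODE[tissue], 102]
    )
    names = list(shares)
    noisy = np.array([shares[n] for n in names]) * _lognormal_factor(
        rng_shares, share_cv, size=len(names)
    )
    noisy = noisy / noisy.sum()

    conc = {n: tac * w for n, w in zip(names, noisy)}
    gl_noise = _lognormal_factor(rng_shares, noise_cv, size=len(glycer))
    for (name, c), f in zip(glycer.items(), gl_noise):
        conc[name] = c * float(f)
    return TissueProfile(
        tissue=tissue,
        stage=stage,
        fresh_weight=fw,
        dw_fraction=dw,
        concentrations=conc,
        replicate=replicate,
    )


def generate_seed_growth_series(
    dw_grid,
    a: float = SEED_POWER_A,
    b: float = SEED_POWER_B,
    noise_cv: float = 0.3,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Seed TAC (mg/gDW) over a dry-weight grid: TAC = a*DW^b * eps."""
    dw_grid = np.asarray(dw_grid, dtype=float)
    if np.any(dw_grid <= 0):
        raise ValueError("dry weights must be positive")
    if a <= 0:
        raise ValueError("coefficient a must be positive")
    rng = np.random.default_rng([int(seed), 202])
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv * noise_cv))
        eps = rng.lognormal(mean=0.0, sigma=sigma, size=dw_grid.size)
    else:
        eps = np.ones(dw_grid.size)
    tac = a * dw_grid ** b * eps
    return list(zip(dw_grid.tolist(), tac.tolist()))


def default_seed_dw_grid(replicates: int = 3) -> np.ndarray:
    return np.repeat([SEED_DW_FRACTION[s] for s in GROWTH_STAGES], replicates)


# --- scan-map synthesis -------------------------------------------------

DEFAULT_ADDUCTS = ("[M+H]+", "[M+Na]+")
DEFAULT_ADDUCT_RESPONSE = (1.0, 0.3)
# chosen so a one-scan RT shift at 0.94 scans/s drops the FWQM-trace
# Pearson correlation below the 0.9 grouping threshold (r ~ 0.88), while a
# zero-shift identical trace correlates at 1
DEFAULT_FWHM_S = 9.0
DEFAULT_RESPONSE_FACTOR = 5.0e4  # counts per (mg/gFW)
_TAIL_FRACTION = 0.002  # truncate Gaussian tails below this fraction of apex
N_BACKGROUND_CHANNELS = 24


def synthesize_scan_map(
    profile: TissueProfile,
    db: list[LipidRecord],
    acq: AcquisitionSettings,
    seed: int,
    adducts=DEFAULT_ADDUCTS,
    adduct_response=DEFAULT_ADDUCT_RESPONSE,
    fwhm_s: float = DEFAULT_FWHM_S,
    response_factor: float = DEFAULT_RESPONSE_FACTOR,
    dropout_p: float = 0.1,
    rt_shift: float = 0.0,
    mz_jitter_sd: float = 0.0,
) -> tuple[ScanMap, GroundTruthLedger]:
    """Render one profile into a centroided scan map plus its ledger.

    Each analyte with a reference record and nonzero concentration yields a
    symmetric Gaussian peak per configured adduct at its nominal elution
    center (plus ``rt_shift``), with a carbon-count isotope envelope spaced
    at 1.00336/z. Dropout (Bernoulli per analyte) suppresses synthesis but
    the suppressed peaks are still ledgered with ``dropped=True``. Peaks
    whose m/z falls outside the acquisition range are skipped and logged.
    """
    sample_key = zlib.crc32(profile.sample_id.encode())  # stable across processes
    rng = np.random.default_rng([int(seed), sample_key, 303])
    times = acq.scan_times()
    n_scans = times.size
    by_name = db_by_name(db)

    ledger = GroundTruthLedger()
    sigma_min = fwhm_s / (2.0 * math.sqrt(2.0 * math.log(2.0))) / 60.0

    peak_mz: list[float] = []
    peak_apex: list[float] = []
    peak_rt: list[float] = []

    analytes = sorted(profile.concentrations)
    dropped_analytes = {
        a for a in analytes if dropout_p > 0 and rng.random() < dropout_p
    }
    for analyte in analytes:
        conc = profile.concentrations[analyte]
        record = by_name.get(analyte)
        if conc <= 0 or record is None:
            continue
        rt_center = record.rt_affinity + rt_shift
        envelope = chem.isotope_envelope(record.formula, 3)
        dropped = analyte in dropped_analytes
        for adduct_label, response in zip(adducts, adduct_response):
            adduct = chem.get_adduct(adduct_label)
            mono_mz = adduct.mz_from_neutral(record.monoisotopic_mass)
            apex = response_factor * conc * response
            if not (acq.mz_min <= mono_mz <= acq.mz_max):
                ledger.skipped.append((profile.sample_id, analyte, adduct_label, mono_mz))
                continue
            ledger.peaks.append(
                LedgerPeak(
                    sample_id=profile.sample_id,
                    analyte=analyte,
                    adduct=adduct_label,
                    charge=adduct.charge,
                    mz=mono_mz,
                    rt_center=rt_center,
                    fwhm_s=fwhm_s,
                    apex_intensity=apex,
                    isotope_abundances=tuple(envelope),
                    dropped=dropped,
                )
            )
            if dropped:
                continue
            for k, abundance in enumerate(envelope):
                mz_k = mono_mz + k * chem.C13_C12_DELTA / adduct.charge
                if not (acq.mz_min <= mz_k <= acq.mz_max):
                    continue
                peak_mz.append(mz_k)
                peak_apex.append(apex * abundance)
                peak_rt.append(rt_center)

    peak_mz_arr = np.array(peak_mz)
    peak_apex_arr = np.array(peak_apex)
    peak_rt_arr = np.array(peak_rt)

    # drifting background channels at fixed m/z positions
    if acq.baseline_amplitude > 0:
        bg_rng = np.random.default_rng([int(seed), 404])
        bg_mz = np.sort(bg_rng.uniform(acq.mz_min, acq.mz_max, N_BACKGROUND_CHANNELS))
        bg_phase = bg_rng.uniform(0, 2 * math.pi, N_BACKGROUND_CHANNELS)
    else:
        bg_mz = np.empty(0)
        bg_phase = np.empty(0)

    scans: list[tuple[np.ndarray, np.ndarray]] = []
    for t in times:
        mz_list = []
        inten_list = []
        if peak_mz_arr.size:
            gauss = peak_apex_arr * np.exp(
                -0.5 * ((t - peak_rt_arr) / sigma_min) ** 2
            )
            keep = gauss >= _TAIL_FRACTION * peak_apex_arr
            if keep.any():
                mz_vals = peak_mz_arr[keep]
                if mz_jitter_sd > 0:
                    mz_vals = mz_vals + rng.normal(0, mz_jitter_sd, mz_vals.size)
                mz_list.append(mz_vals)
                inten_list.append(gauss[keep])
        if bg_mz.size:
            drift = acq.baseline_amplitude * (
                0.6 + 0.4 * np.sin(2 * math.pi * t / acq.gradient_length + bg_phase)
            )
            mz_list.append(bg_mz)
            inten_list.append(drift)
        if mz_list:
            mz_arr = np.concatenate(mz_list)
            inten_arr = np.concatenate(inten_list)
            if acq.noise_sd > 0:
                inten_arr = inten_arr + rng.normal(0, acq.noise_sd, inten_arr.size)
                inten_arr = np.clip(inten_arr, 0.0, None)
            order = np.argsort(mz_arr)
            scans.append((mz_arr[order], inten_arr[order]))
        else:
            scans.append((np.empty(0), np.empty(0)))

    return ScanMap(times, scans, sample_id=profile.sample_id), ledger


# --- UV peak-area synthesis ---------------------------------------------


def synthesize_uv_peak_table(
    profile: TissueProfile,
    seed: int,
    curves=None,
    noise_cv: float = 0.0,
) -> dict[str, float]:
    """220-nm peak areas for the targeted acetogenin analytes.

    Persin and Persenone B co-elute: if the profile carries them as
    separate entries they are emitted as one merged area under the
    Persenone B (merged-analyte) response.
    """
    from .quant import default_calibration  # local import to avoid cycle

    if curves is None:
        curves = default_calibration()
    rng = np.random.default_rng([int(seed), profile.replicate, 505])
    conc = dict(profile.concentrations)
    merged = conc.pop("Persin", 0.0) + conc.pop("Persenone B", 0.0)
    if merged:
        conc["Persin/Persenone B"] = conc.get("Persin/Persenone B", 0.0) + merged

    areas: dict[str, float] = {}
    for analyte in ACETOGENIN_ANALYTES:
        curve = curves[analyte]
        c = conc.get(analyte, 0.0)
        factor = 1.0 + (rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0)
        areas[analyte] = curve.intercept + curve.slope * c * factor if c > 0 else 0.0
    return areas
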