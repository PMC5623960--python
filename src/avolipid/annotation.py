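"""Putative identity assignment: adduct hypothesis enumeration, reference
database search, isotope-pattern verification, and hierarchical
class-composition weighting ('fixed' vs 'approximate').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from . import chem
from .grouping import FeatureGroup, has_acetoxy_loss_pair
from .synthetic import LipidRecord

logger = logging.getLogger(__name__)

PPM_WINDOW = 25.0  # added to 3 sd of the m/z measurement
ISOTOPE_INTENSITY_MARGIN = 0.05


@dataclass(frozen=True)
class AdductHypothesis:
    """A candidate ion species converting an observed m/z to a neutral mass."""

    label: str
    components: tuple[str, ...]
    charge: int
    neutral_mass: float
    observed_mz: float
    duplicate_mass: bool = False

    def recompute_mz(self) -> float:
        shift = sum(chem.ADDUCT_COMPONENT_MASS[c] for c in self.components)
        return (self.neutral_mass + shift - self.charge * chem.ELECTRON_MASS) / self.charge


@dataclass
class AnnotationCandidate:
    feature_id: int
    record: LipidRecord
    adduct_label: str
    charge: int
    neutral_mass: float
    mass_error_ppm: float
    isotope_check: str = "untested"  # {"pass", "fail", "untested"}


@dataclass
class CompositionProfile:
    """Per-level lipid-class weight vectors for one feature."""

    level: int
    weights: dict[str, float] = field(default_factory=dict)
    fixed: bool = False
    annotated: bool = True

    def __post_init__(self):
        if self.weights:
            total = sum(self.weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition weights sum to {total}, not 1")


def enumerate_adducts(mean_mz: float, charge: int) -> list[AdductHypothesis]:
    """Enumerate positive-mode adduct hypotheses for one observed m/z.

    Charge 1 yields exactly 4 hypotheses (H, NH4, Na, K); charge 2 yields
    the 16 ordered pairings of those components. Hypotheses whose neutral
    mass duplicates an earlier one are retained but flagged.
    """
    if charge == 1:
        combos = [(c,) for c in chem.ADDUCT_COMPONENTS]
    elif charge == 2:
        combos = [tuple(p) for p in product(chem.ADDUCT_COMPONENTS, repeat=2)]
    else:
        raise ValueError(f"unsupported charge {charge}; expected 1 or 2")
    hypotheses: list[AdductHypothesis] = []
    seen_masses: list[float] = []
    for components in combos:
        adduct = chem.Adduct(components)
        neutral = adduct.neutral_from_mz(mean_mz)
        duplicate = any(abs(neutral - m) < 1e-9 for m in seen_masses)
        seen_masses.append(neutral)
        hypotheses.append(
            AdductHypothesis(
                label=adduct.label,
                components=components,
                charge=charge,
                neutral_mass=neutral,
                observed_mz=mean_mz,
                duplicate_mass=duplicate,
            )
        )
    return hypotheses


def search_db(
    hypotheses: list[AdductHypothesis],
    db: list[LipidRecord],
    mz_sd: float,
    feature_id: int = -1,
) -> list[AnnotationCandidate]:
    """Match hypotheses against the reference database.

    A record matches when |record mass - neutral mass| is at most
    3*mz_sd*charge + 25 ppm of the neutral mass.
    """
    if not db:
        logger.warning("search_db called with an empty reference database")
        return []
    candidates = []
    for hyp in hypotheses:
        window = 3.0 * mz_sd * hyp.charge + PPM_WINDOW * 1e-6 * hyp.neutral_mass
        for record in db:
            err = record.monoisotopic_mass - hyp.neutral_mass
            if abs(err) <= window:
                candidates.append(
                    AnnotationCandidate(
                        feature_id=feature_id,
                        record=record,
                        adduct_label=hyp.label,
                        charge=hyp.charge,
                        neutral_mass=hyp.neutral_mass,
                        mass_error_ppm=1e6 * err / hyp.neutral_mass,
                    )
                )
    return candidates


def theoretical_envelope(candidate: AnnotationCandidate, n_isotopologues: int = 3) -> list[float]:
    """Relative isotopologue intensities of the candidate ion (with adduct atoms)."""
    counts = dict(candidate.record.formula)
    adduct = chem.get_adduct(candidate.adduct_label)
    for comp in adduct.components:
        for el, n in chem.parse_formula(comp).items():
            counts[el] = counts.get(el, 0) + n
    return chem.isotope_envelope(counts, n_isotopologues)


def verify_isotopes(
    candidate: AnnotationCandidate,
    observed_envelope: list[tuple[float, float, float]],
) -> bool:
    """Check the candidate's theoretical envelope against observation.

    ``observed_envelope``: per isotopologue beyond the monoisotopic peak,
    (relative intensity mean, intensity sd, correlation r to the
    monoisotopic trace). The allowed window per isotopologue is
    sd / r^2 + 5% of the intensity value; r == 0 makes the window
    degenerate and fails the check.
    """
    theory = theoretical_envelope(candidate, n_isotopologues=len(observed_envelope) + 1)
    result = True
    for k, (mean, sd, r) in enumerate(observed_envelope, start=1):
        if r == 0:
            logger.warning("degenerate isotope window (r=0) for %s", candidate.record.record_id)
            result = False
            break
        window = sd / (r * r) + ISOTOPE_INTENSITY_MARGIN * mean
        if abs(theory[k] - mean) > window:
            result = False
            break
    candidate.isotope_check = "pass" if result else "fail"
    return result


def classify_composition(
    candidates: list[AnnotationCandidate], level: int
) -> CompositionProfile:
    """Class-composition weights over surviving candidates at one level.

    Each candidate compound contributes equally; the profile is 'fixed'
    when a single class holds all candidates.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"unknown hierarchy level {level}")
    if not candidates:
        logger.warning("classify_composition: no surviving candidates")
        return CompositionProfile(level=level, weights={}, fixed=False, annotated=False)
    classes = [c.record.class_at_level(level) for c in candidates]
    total = len(classes)
    weights = {cls: classes.count(cls) / total for cls in sorted(set(classes))}
    return CompositionProfile(level=level, weights=weights, fixed=len(weights) == 1)


@dataclass
class SignatureReport:
    group_members: list[int]
    has_odd_carbon_high_oxygen: bool
    has_acetoxy_loss: bool

    @property
    def putative_acetogenin(self) -> bool:
        return self.has_odd_carbon_high_oxygen and self.has_acetoxy_loss


def flag_acetogenin_signatures(
    group: FeatureGroup,
    candidates: list[AnnotationCandidate],
    features=None,
) -> SignatureReport:
    """Flag a group as putative acetogenin.

    Requires (a) some candidate formula with O >= 4 and an odd carbon
    count, and (b) an acetoxy-loss fragment pair within the group.
    """
    odd_high_o = any(
        c.record.formula.get("O", 0) >= 4 and c.record.formula.get("C", 0) % 2 == 1
        for c in candidates
    )
    acetoxy = (
        has_acetoxy_loss_pair(group, features) if features is not None else False
    )
    return SignatureReport(
        group_members=list(group.member_ids),
        has_odd_carbon_high_oxygen=odd_high_o,
        has_acetoxy_loss=acetoxy,
    )


def observed_envelope_from_features(
    monoisotopic, isotopologues
) -> list[tuple[float, float, float]]:
    """Summarize detected isotopologue traces relative to the monoisotopic one.

    For each isotopologue feature co-traced with the monoisotopic feature,
    returns (mean relative intensity, sd of relative intensity,
    Pearson r to the monoisotopic trace) over the shared scans.
    """
    from .grouping import trace_correlation

    out = []
    base = monoisotopic
    for iso in isotopologues:
        r = trace_correlation(base, iso)
        # align on shared scan stamps
        ratios = []
        for t, inten in zip(iso.trace_times, iso.trace_intensities):
            k = np.argmin(np.abs(base.trace_times - t))
            if abs(base.trace_times[k] - t) < 1e-6 and base.trace_intensities[k] > 0:
                ratios.append(inten / base.trace_intensities[k])
        if not ratios:
            out.append((0.0, 0.0, 0.0))
            continue
        out.append((float(np.mean(ratios)), float(np.std(ratios)), float(r) if r is not None else 0.0))
    return out
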