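import numpy as np
import pytest

from avolipid import signal, synthetic as syn


@pytest.fixture(scope="session")
def lipid_db():
    return syn.generate_lipid_db(seed=1)


@pytest.fixture(scope="session")
def small_acq():
    """Short, narrow acquisition for fast signal-processing tests."""
    return syn.AcquisitionSettings(
        mz_min=150, mz_max=1200, scan_rate=0.94, gradient_length=60
    )


@pytest.fixture(scope="session")
def clean_profile():
    return syn.generate_sample_profile(
        "mesocarp", "unripe", seed=1, noise_cv=0.0, share_cv=0.0
    )


@pytest.fixture(scope="session")
def clean_map_and_ledger(clean_profile, lipid_db, small_acq):
    return syn.synthesize_scan_map(
        clean_profile, lipid_db, small_acq, seed=1, dropout_p=0.0
    )


@pytest.fixture(scope="session")
def clean_features(clean_map_and_ledger):
    scan_map, _ = clean_map_and_ledger
    feats = signal.detect_peaks(scan_map)
    signal.group_isotopes(feats)
    return feats


def gaussian_trace_feature(
    feature_id: int,
    mz: float,
    rt_center: float,
    apex: float,
    fwhm_s: float = syn.DEFAULT_FWHM_S,
    scan_rate: float = 0.94,
    sample_id: str = "s",
    shift_scans: int = 0,
):
    """Hand-built PeakFeature with an exact Gaussian FWQM trace."""
    sigma_min = fwhm_s / 2.3548200450309493 / 60.0
    dt = 1.0 / scan_rate / 60.0
    center = rt_center + shift_scans * dt
    half = 1.6651092223153954 * sigma_min  # quarter-max half-width
    n = int(np.floor(half / dt))
    times = rt_center + np.arange(-n, n + 1) * dt
    inten = apex * np.exp(-0.5 * ((times - center) / sigma_min) ** 2)
    return signal.PeakFeature(
        sample_id=sample_id,
        mean_mz=mz,
        mz_sd=1e-3,
        rt_apex=float(center),
        fwqm_bounds=(float(times[0]), float(times[-1])),
        trace_times=times,
        trace_intensities=inten,
        area=float(np.trapezoid(inten, times * 60.0)),
        feature_id=feature_id,
    )
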