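"""The 26-feature bank computed per record and per frequency band.

Eleven wavelet features from a single db4 decomposition step
(approximation/detail energies, their Shannon entropies, and five
entropy normalizations), six band-power features (absolute and relative
band power plus four cross-band normalizations), Higuchi fractal
dimension, the leading Burg autoregressive coefficient, positive and
negative peak amplitudes, three summary statistics, and two demographic
indicators.

Normalization identities that hold for every valid record, per band set:

* ``R-ApEn + R-DeEn = 1`` whenever total wavelet entropy is positive,
* ``ApEn-0 + DeEn-0 = 2`` and ``max(ApEn-1, DeEn-1) = 1``,
* ``sum over bands of RBP = 100`` (percent),
* ``max over bands of ABP-0 = 1`` and ``mean over bands of ABP-1 = 1``,
* ``PPA >= 0 >= NPA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from statsmodels.regression.linear_model import burg as _burg

from .preprocessing import BANDS, BandSet, decompose_bands, reject_artifacts
from .synthetic import BAND_NAMES, ERPRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "FeatureOptions",
    "dwt_features",
    "band_power_features",
    "fractal_dimension",
    "ar_feature",
    "peak_amplitudes",
    "summary_features",
    "record_features",
    "extract_feature_tables",
    "coefficient_entropy",
]

#: Canonical feature order used by every table, grid and pattern.
FEATURE_NAMES: tuple[str, ...] = (
    "WT-ApCo",
    "WT-DeCo",
    "ApEn",
    "DeEn",
    "TotalWE",
    "R-ApEn",
    "R-DeEn",
    "ApEn-0",
    "DeEn-0",
    "ApEn-1",
    "DeEn-1",
    "ABP",
    "RBP",
    "ABP-0",
    "ABP-1",
    "RBP-0",
    "RBP-1",
    "FD",
    "AR",
    "PPA",
    "NPA",
    "Sum",
    "Average",
    "Median",
    "Gender",
    "FirstChild",
)

KEY_COLUMNS = ("subject_id", "modality", "electrode")
LABEL_COLUMN = "group"


@dataclass(frozen=True)
class FeatureOptions:
    """Tunable knobs of the feature bank.

    wavelet : mother wavelet of the single-level decomposition.
    ar_order : order of the Burg fit; the returned AR feature is the
        first (lag-1) coefficient.
    fd_kmax : largest interval in the Higuchi curve-length regression.
    entropy_norm : how ApEn-1/DeEn-1 are normalized — ``"pair-max"``
        divides by max(ApEn, DeEn); ``"theoretical"`` divides by the
        maximum-entropy bound ln(N) of each coefficient set.
    rbp_mode : ``"amplitude"`` computes relative band power from mean
        absolute amplitudes; ``"power"`` from mean squared amplitudes.
    """

    wavelet: str = "db4"
    ar_order: int = 6
    fd_kmax: int = 8
    entropy_norm: str = "pair-max"
    rbp_mode: str = "amplitude"


class ZeroSignalError(ValueError):
    """Raised for features undefined on an all-zero signal."""


def coefficient_entropy(coeffs: np.ndarray) -> float:
    """Shannon entropy (nats) of the normalized energy distribution
    p_i = c_i^2 / sum(c^2) over a coefficient vector."""
    c = np.asarray(coeffs, dtype=float)
    energy = c**2
    total = energy.sum()
    if total <= 0:
        raise ZeroSignalError("entropy undefined for zero-energy coefficients")
    p = energy / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def dwt_features(
    band_signal: np.ndarray, options: FeatureOptions = FeatureOptions()
) -> dict[str, float]:
    """Eleven features from one wavelet decomposition step.

    The signal splits into approximation (low-frequency) and detail
    (high-frequency) coefficients; WT-ApCo / WT-DeCo are their mean
    squared values (energy per coefficient), ApEn / DeEn the Shannon
    entropies of each set's energy distribution, and the rest are the
    stated combinations and normalizations of those two entropies.
    """
    x = np.asarray(band_signal, dtype=float)
    w = pywt.Wavelet(options.wavelet)
    if len(x) < 2 * w.dec_len:
        raise ValueError(
            f"signal ({len(x)} samples) too short for one {options.wavelet} "
            "decomposition step"
        )
    ca, cd = pywt.dwt(x, w)
    ap_en = coefficient_entropy(ca)
    de_en = coefficient_entropy(cd)
    total_we = ap_en + de_en
    mean_en = total_we / 2.0
    if options.entropy_norm == "pair-max":
        ap_norm1 = max(ap_en, de_en)
        de_norm1 = ap_norm1
    elif options.entropy_norm == "theoretical":
        ap_norm1 = np.log(len(ca))
        de_norm1 = np.log(len(cd))
    else:
        raise ValueError(f"unknown entropy_norm {options.entropy_norm!r}")
    return {
        "WT-ApCo": float(np.mean(ca**2)),
        "WT-DeCo": float(np.mean(cd**2)),
        "ApEn": ap_en,
        "DeEn": de_en,
        "TotalWE": total_we,
        "R-ApEn": ap_en / total_we,
        "R-DeEn": de_en / total_we,
        "ApEn-0": ap_en / mean_en,
        "DeEn-0": de_en / mean_en,
        "ApEn-1": ap_en / ap_norm1,
        "DeEn-1": de_en / de_norm1,
    }


def band_power_features(
    band_set: BandSet, options: FeatureOptions = FeatureOptions()
) -> dict[str, dict[str, float]]:
    """Six power features per band from one decomposed record.

    ABP[b] is the mean squared sample of band b.  RBP[b] is band b's
    percentage share of summed across-band amplitude (mean |x| by
    default).  ABP-0 / ABP-1 normalize ABP by the across-band maximum and
    mean; RBP-0 / RBP-1 normalize RBP by the maximum and mean squared
    sample of the *raw* signal.
    """
    abp = {b: float(np.mean(band_set.bands[b] ** 2)) for b in BAND_NAMES}
    if options.rbp_mode == "amplitude":
        amp = {b: float(np.mean(np.abs(band_set.bands[b]))) for b in BAND_NAMES}
    elif options.rbp_mode == "power":
        amp = abp
    else:
        raise ValueError(f"unknown rbp_mode {options.rbp_mode!r}")
    total_amp = sum(amp.values())
    raw_sq = np.asarray(band_set.raw, dtype=float) ** 2
    raw_max = float(raw_sq.max(initial=0.0))
    raw_mean = float(raw_sq.mean()) if raw_sq.size else 0.0
    if total_amp <= 0 or raw_max <= 0 or raw_mean <= 0:
        raise ZeroSignalError("band-power ratios undefined for an all-zero record")
    abp_max = max(abp.values())
    abp_mean = sum(abp.values()) / len(abp)
    out: dict[str, dict[str, float]] = {}
    for b in BAND_NAMES:
        rbp = 100.0 * amp[b] / total_amp
        out[b] = {
            "ABP": abp[b],
            "RBP": rbp,
            "ABP-0": abp[b] / abp_max,
            "ABP-1": abp[b] / abp_mean,
            "RBP-0": rbp / raw_max,
            "RBP-1": rbp / raw_mean,
        }
    return out


def fractal_dimension(band_signal: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension.

    Reconstructs k-subsampled curves for k = 1..kmax, averages the
    normalized curve length L(k) over offsets, and returns the negative
    slope of ln L(k) against ln k.  A straight line has dimension 1,
    white noise approaches 2; a constant signal returns 1 by convention.
    """
    x = np.asarray(band_signal, dtype=float)
    n = len(x)
    if n < 2 * kmax:
        raise ValueError(f"signal too short for Higuchi FD with kmax={kmax}")
    if np.ptp(x) == 0:
        return 1.0
    ks = np.arange(1, kmax + 1)
    lengths = np.empty(kmax)
    for i, k in enumerate(ks):
        lk = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)
            lk.append(dist * norm / k)
        lengths[i] = np.mean(lk)
    slope = np.polyfit(np.log(ks), np.log(lengths), 1)[0]
    return float(-slope)


def ar_feature(band_signal: np.ndarray, order: int = 6) -> float:
    """First coefficient of an AR(order) model fitted by Burg's method.

    Positive sign convention: x_t = a_1 x_{t-1} + ... + a_p x_{t-p} + e_t;
    the returned scalar is a_1.
    """
    x = np.asarray(band_signal, dtype=float)
    if len(x) <= 2 * order:
        raise ValueError(f"signal too short for AR({order}) fit")
    if np.ptp(x) == 0:
        raise ZeroSignalError("AR fit undefined for a constant signal")
    coefs, _sigma2 = _burg(x - x.mean(), order=order)
    return float(coefs[0])


def peak_amplitudes(band_signal: np.ndarray) -> tuple[float, float]:
    """Positive/negative peak amplitude relative to the signal mid-point
    (the mean): PPA = max - mean >= 0 >= NPA = min - mean."""
    x = np.asarray(band_signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    mid = float(x.mean())
    return float(x.max() - mid), float(x.min() - mid)


def summary_features(band_signal: np.ndarray) -> tuple[float, float, float]:
    """(Sum, Average, Median) of the samples."""
    x = np.asarray(band_signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return float(x.sum()), float(x.mean()), float(np.median(x))


def record_features(
    record: ERPRecord,
    band_set: BandSet,
    options: FeatureOptions = FeatureOptions(),
) -> dict[str, dict[str, float]]:
    """All 26 features of one record, keyed band -> feature name."""
    power = band_power_features(band_set, options)
    gender = 1.0 if record.gender == "M" else 0.0
    first_child = 1.0 if record.first_child else 0.0
    out: dict[str, dict[str, float]] = {}
    for band in BAND_NAMES:
        sig = band_set.bands[band]
        feats = dict(dwt_features(sig, options))
        feats.update(power[band])
        feats["FD"] = fractal_dimension(sig, options.fd_kmax)
        feats["AR"] = ar_feature(sig, options.ar_order)
        ppa, npa = peak_amplitudes(sig)
        feats["PPA"] = ppa
        feats["NPA"] = npa
        s, a, m = summary_features(sig)
        feats["Sum"] = s
        feats["Average"] = a
        feats["Median"] = m
        feats["Gender"] = gender
        feats["FirstChild"] = first_child
        out[band] = {name: feats[name] for name in FEATURE_NAMES}
    return out


def extract_feature_tables(
    records: list[ERPRecord],
    options: FeatureOptions = FeatureOptions(),
    artifact_threshold_uv: float = 100.0,
    preprocess: bool = True,
) -> dict[str, pd.DataFrame]:
    """One feature table per band from a cohort of records.

    Each record is artifact-cleaned, band-decomposed and featurized; rows
    whose features are undefined (e.g. an unusable record) are excluded
    with a logged count.  Columns: the three row keys, the class label,
    then the 26 features in canonical order.
    """
    rows: dict[str, list[dict]] = {b: [] for b in BAND_NAMES}
    n_failed = 0
    for record in records:
        try:
            if preprocess:
                cleaned, _n_rej = reject_artifacts(record, artifact_threshold_uv)
            else:
                cleaned = record
            band_set = decompose_bands(cleaned, BANDS)
            per_band = record_features(cleaned, band_set, options)
        except (ValueError, ZeroSignalError) as exc:
            n_failed += 1
            logger.warning(
                "excluding record %s/%s/%s: %s",
                record.subject_id,
                record.modality,
                record.electrode,
                exc,
            )
            continue
        for band in BAND_NAMES:
            row = {
                "subject_id": record.subject_id,
                "modality": record.modality,
                "electrode": record.electrode,
                LABEL_COLUMN: record.group_label,
            }
            row.update(per_band[band])
            rows[band].append(row)
    if n_failed:
        logger.info("excluded %d records with undefined features", n_failed)
    columns = list(KEY_COLUMNS) + [LABEL_COLUMN] + list(FEATURE_NAMES)
    return {
        band: pd.DataFrame(rows[band], columns=columns) for band in BAND_NAMES
    }
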