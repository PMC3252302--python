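"""Component selection by spectral power.

Resting-state networks carry their power in the very-low-frequency band; a
component whose time-course power above 0.1 Hz exceeds 50% of the total is
treated as artifactual and discarded. The fraction is aggregated across
subjects by the median. Visual inspection is replaced by an optional manual
override list (ids to force-keep or force-discard).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpectralProfile", "spectral_fraction", "select_components",
           "SelectionReport"]


@dataclass
class SpectralProfile:
    """One-sided periodogram of a component time course.

    ``power`` is scaled so that its sum over non-DC bins equals the
    time-domain variance (Parseval); ``high_freq_fraction`` is the share of
    that variance above the cutoff.
    """

    freqs: np.ndarray
    power: np.ndarray
    high_freq_fraction: float


@dataclass
class SelectionReport:
    table: pd.DataFrame          # component, fraction, kept, overridden
    kept: list[int]


def spectral_fraction(tc: np.ndarray, tr_s: float,
                      cutoff_hz: float = 0.1) -> SpectralProfile:
    """Fraction of a time course's power above ``cutoff_hz``.

    Uses the raw periodogram of the demeaned series; DC is excluded from the
    total. Requires the Nyquist frequency to exceed the cutoff.
    """
    x = np.asarray(tc, dtype=float)
    if x.ndim != 1:
        raise ValueError("tc must be 1D")
    n = x.shape[0]
    if n < 8:
        raise ValueError("need at least 8 time points")
    nyq = 0.5 / tr_s
    if nyq <= cutoff_hz:
        raise ValueError(
            f"Nyquist {nyq} Hz <= cutoff {cutoff_hz} Hz; TR too long")
    x = x - x.mean()
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=tr_s)
    # one-sided power normalized so sum over f>0 equals time-domain variance
    power = np.abs(spec) ** 2 / n ** 2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0           # Nyquist bin is not duplicated
    total = power[1:].sum()
    frac = 0.0 if total <= 0 else float(power[freqs > cutoff_hz].sum() / total)
    return SpectralProfile(freqs=freqs, power=power, high_freq_fraction=frac)


def select_components(subject_tcs: list[np.ndarray], tr_s: float,
                      cutoff_hz: float = 0.1, max_fraction: float = 0.5,
                      force_keep: list[int] | None = None,
                      force_discard: list[int] | None = None,
                      ) -> SelectionReport:
    """Keep components whose median (across subjects) high-frequency power
    fraction does not exceed ``max_fraction`` (strict '> 50%' discard rule).

    ``subject_tcs`` is a list of (time, K) matrices, one per subject.
    Overrides are honored after the rule and recorded in the report.
    """
    if not subject_tcs:
        raise ValueError("need at least one subject")
    K = subject_tcs[0].shape[1]
    if K < 1:
        raise ValueError("need at least one component")
    force_keep = set(force_keep or [])
    force_discard = set(force_discard or [])
    fracs = np.empty((len(subject_tcs), K))
    for s, tcs in enumerate(subject_tcs):
        if tcs.shape[1] != K:
            raise ValueError("subjects disagree on component count")
        for k in range(K):
            fracs[s, k] = spectral_fraction(tcs[:, k], tr_s,
                                            cutoff_hz).high_freq_fraction
    med = np.median(fracs, axis=0)
    rows = []
    kept = []
    for k in range(K):
        keep = not med[k] > max_fraction       # fraction exactly at 0.5 kept
        overridden = False
        if k in force_discard:
            keep, overridden = False, True
        elif k in force_keep:
            keep, overridden = True, True
        if keep:
            kept.append(k)
        rows.append({"component": k, "high_freq_fraction": float(med[k]),
                     "kept": keep, "overridden": overridden})
    if not kept:
        raise ValueError(
            "all components discarded by the spectral rule; inspect the "
            "time courses or supply a force_keep override")
    return SelectionReport(table=pd.DataFrame(rows), kept=kept)
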