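"""Activity normalization and LOF / neutral / GOF functional classification.

Raw plate signals are normalized as (mutant - background) / (WT - background)
per substrate channel (unmodified ``me0`` and monomethylated ``me1``).  A
variant is loss-of-function when its primary-channel activity drops below 50%
of wild type.  Gain-of-function is called against the *neutral band* — mean
and 1-sigma of activities among variants retaining > 50% of wild-type activity
— either as a plain gain (activity above mean + ``gof_sigma``·sigma on either
channel) or as a switch (primary channel lost while the other channel exceeds
its band), the pattern shown by product-specificity-switch mutants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOF, NEUTRAL, GOF = "LOF", "neutral", "GOF"
CHANNELS = ("me0", "me1")


class AssayError(ValueError):
    """Unusable raw signal (wild-type signal at or below background)."""


def normalize_activity(mutant_signal: float, wt_signal: float,
                       background_signal: float = 0.0) -> float:
    """Background-subtracted mutant/WT ratio, floored at 0."""
    if wt_signal <= background_signal:
        raise AssayError(
            f"wild-type signal {wt_signal} not above background {background_signal}")
    return max(0.0, (mutant_signal - background_signal)
               / (wt_signal - background_signal))


def aggregate_replicates(ratios) -> tuple[float, float]:
    """Mean and sample standard deviation over replicates (sd 0 for a single one)."""
    r = np.asarray(list(ratios), dtype=float)
    if r.size == 0:
        raise ValueError("need at least one replicate")
    sd = float(r.std(ddof=1)) if r.size > 1 else 0.0
    return float(r.mean()), sd


@dataclass
class NeutralBand:
    """Per-channel mean and 1-sigma of activities among variants with activity > 0.5."""

    mean: dict[str, float]
    sd: dict[str, float]
    n: dict[str, int]

    def upper(self, channel: str, sigma: float = 1.0) -> float:
        return self.mean[channel] + sigma * self.sd[channel]


def neutral_band(activity_me0, activity_me1=None, min_active: float = 0.5) -> NeutralBand:
    """Neutral reference band from the > ``min_active`` subset, per channel."""
    channels = {"me0": np.asarray(activity_me0, dtype=float)}
    if activity_me1 is not None:
        channels["me1"] = np.asarray(activity_me1, dtype=float)
    mean, sd, n = {}, {}, {}
    for ch, a in channels.items():
        sub = a[a > min_active]
        if len(sub) < 2:
            raise ValueError(
                f"neutral band needs >= 2 variants with {ch} activity > {min_active}")
        mean[ch] = float(sub.mean())
        sd[ch] = float(sub.std(ddof=1))
        n[ch] = int(len(sub))
    return NeutralBand(mean, sd, n)


def classify_variant(activity_me0: float, activity_me1: float | None,
                     band: NeutralBand, lof_threshold: float = 0.5,
                     gof_sigma: float = 2.0,
                     primary: str = "me0") -> tuple[str, str | None]:
    """Assign exactly one of LOF / neutral / GOF, with GOF mode gain or switch.

    GOF takes precedence: a variant whose activity exceeds the neutral band by
    ``gof_sigma`` sigma on either channel is a gain, and one losing the primary
    channel while exceeding the band on the other is a switch; otherwise the
    strict < ``lof_threshold`` rule on the primary channel makes it LOF.
    """
    acts = {"me0": activity_me0, "me1": activity_me1}
    if primary not in CHANNELS:
        raise ValueError(f"unknown primary channel {primary!r}")
    prim = acts[primary]
    other = "me1" if primary == "me0" else "me0"
    for ch in CHANNELS:
        if acts[ch] is not None and ch in band.mean \
                and acts[ch] > band.upper(ch, gof_sigma):
            if prim < lof_threshold and ch == other:
                return GOF, "switch"
            return GOF, "gain"
    if prim < lof_threshold:
        return LOF, None
    return NEUTRAL, None


def classify_table(df: pd.DataFrame, lof_threshold: float = 0.5,
                   gof_sigma: float = 2.0, primary: str = "me0",
                   band: NeutralBand | None = None) -> tuple[pd.DataFrame, NeutralBand]:
    """Label every variant of a table; returns (labels frame, band used)."""
    me1 = df["activity_me1"] if "activity_me1" in df.columns else None
    if band is None:
        band = neutral_band(df["activity_me0"], me1, min_active=lof_threshold)
    labels, modes = [], []
    for i in range(len(df)):
        lab, mode = classify_variant(
            float(df["activity_me0"].iloc[i]),
            None if me1 is None else float(me1.iloc[i]),
            band, lof_threshold, gof_sigma, primary)
        labels.append(lab)
        modes.append(mode)
    out = pd.DataFrame({"label": labels, "gof_mode": modes}, index=df.index)
    return out, band
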