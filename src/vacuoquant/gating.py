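"""Lymphocyte subset gating and affected-fraction quantification.

Subsets are assigned from 1-D marker thresholds with a fixed precedence:
CD20+ events are B cells; otherwise CD3+ events are T cells, split into CD4+
(T4) and CD8+ (T8); otherwise CD56+ events are NK cells; everything else is
"other".  The positivity gate for intracellular lysosomal accumulation is
anchored on the NK population, which constitutively expresses both LAMP-1
and perforin and therefore serves as an internal positive control within
each sample: the LAMP-1 and perforin gates are placed at a lower quantile
(default the 5th percentile) of the NK intensities.  An event is *affected*
— storing, rather than cytotoxically activated — when it is LAMP-1 positive
AND perforin negative; LAMP-1-high perforin-high events indicate cytotoxic
activation and are deliberately excluded.

Marker positivity thresholds default to an Otsu split of each channel's
(log-scale) intensity histogram, reusing the imaging module's thresholding
primitive so the whole package has a single thresholding rule.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .imaging import otsu_threshold

__all__ = [
    "GateSet",
    "SubsetReport",
    "auto_marker_gates",
    "assign_subsets",
    "derive_lamp1_gate",
    "affected_fractions",
    "continuous_otsu",
]

MARKER_CHANNELS = ("CD3", "CD4", "CD8", "CD20", "CD56")
LYMPHOCYTE_SUBSETS = ("B", "T4", "T8", "NK")


@dataclass
class GateSet:
    """1-D thresholds for subset assignment and LAMP-1/perforin positivity."""

    cd3_threshold: float
    cd4_threshold: float
    cd8_threshold: float
    cd20_threshold: float
    cd56_threshold: float
    lamp1_gate: float = math.nan
    perforin_gate: float = math.nan
    lamp1_gate_source: str = "manual"

    def threshold_for(self, channel: str) -> float:
        return getattr(self, f"{channel.lower()}_threshold")


@dataclass
class SubsetReport:
    """Per-subset affected percentages for one sample.

    ``subsets`` maps B/T4/T8/NK to dicts with ``n_events``, ``n_affected``
    and ``pct_affected`` (``None`` when the subset has no events — missing,
    not zero).  The NK entry is reported but flagged: it is the positive
    control population, not a disease readout.
    """

    sample_id: str
    subsets: dict = field(default_factory=dict)
    control_population: str = "NK"

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "control_population": self.control_population,
            "subsets": self.subsets,
        }


def continuous_otsu(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu split point of a continuous 1-D sample.

    Values are binned into ``nbins`` equal-width bins over their range; the
    8-bit Otsu primitive finds the splitting bin and the returned threshold
    is that bin's left edge mapped back to data units.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 finite values")
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise ValueError("constant channel: no threshold exists")
    width = (hi - lo) / nbins
    idx = np.minimum(((v - lo) / width).astype(np.int64), nbins - 1)
    level = otsu_threshold(idx)
    return lo + level * width


def _require_channels(events: pd.DataFrame, channels: tuple[str, ...]) -> None:
    for ch in channels:
        if ch not in events.columns:
            raise ValueError(f"missing channel: {ch}")


def auto_marker_gates(events: pd.DataFrame) -> GateSet:
    """Derive surface-marker positivity thresholds per channel via Otsu.

    Assumes each marker channel is bimodal (a negative and a positive
    population present in the sample).  LAMP-1/perforin gates are left unset;
    derive them with :func:`derive_lamp1_gate` after subset assignment.
    """
    _require_channels(events, MARKER_CHANNELS)
    kwargs = {
        f"{ch.lower()}_threshold": continuous_otsu(events[ch].to_numpy())
        for ch in MARKER_CHANNELS
    }
    return GateSet(**kwargs)


def assign_subsets(events: pd.DataFrame, gates: GateSet) -> pd.DataFrame:
    """Label every event with exactly one subset.

    Precedence: CD20+ -> B; else CD3+ -> T, split into T4/T8 by CD4/CD8
    positivity; else CD56+ -> NK; else other.  CD4+CD8+ double-positive T
    cells go to the marker with the larger standardized excess above its
    threshold (channel SD as scale), ties to T4.  CD3+ events positive for
    neither CD4 nor CD8 fall through to "other".  Returns a copy of the
    table with a ``subset`` column.
    """
    _require_channels(events, MARKER_CHANNELS)
    cd20 = events["CD20"].to_numpy() >= gates.cd20_threshold
    cd3 = events["CD3"].to_numpy() >= gates.cd3_threshold
    cd4 = events["CD4"].to_numpy() >= gates.cd4_threshold
    cd8 = events["CD8"].to_numpy() >= gates.cd8_threshold
    cd56 = events["CD56"].to_numpy() >= gates.cd56_threshold

    sd4 = float(events["CD4"].std()) or 1.0
    sd8 = float(events["CD8"].std()) or 1.0
    exc4 = (events["CD4"].to_numpy() - gates.cd4_threshold) / sd4
    exc8 = (events["CD8"].to_numpy() - gates.cd8_threshold) / sd8

    labels = np.full(len(events), "other", dtype=object)
    t = ~cd20 & cd3
    labels[t & cd4 & ~cd8] = "T4"
    labels[t & cd8 & ~cd4] = "T8"
    dp = t & cd4 & cd8
    labels[dp] = np.where(exc4[dp] >= exc8[dp], "T4", "T8")
    labels[~cd20 & ~cd3 & cd56] = "NK"
    labels[cd20] = "B"

    out = events.copy()
    out["subset"] = labels
    return out


def derive_lamp1_gate(
    labeled: pd.DataFrame,
    gates: GateSet,
    quantile: float = 0.05,
    min_nk: int = 50,
) -> GateSet:
    """Anchor the LAMP-1 and perforin gates on the NK internal control.

    Both gates are set to the given lower quantile (default 5th percentile)
    of the NK population's LAMP-1 and perforin intensities.  The quantile is
    the order statistic at-or-below the nominal level (``method="lower"``),
    which guarantees that at least ``1 - quantile`` of NK events are positive
    on each marker by construction.  Requires at least ``min_nk`` NK events;
    otherwise raises with the advice to set manual gates.
    """
    _require_channels(labeled, ("LAMP1", "PERFORIN"))
    if "subset" not in labeled.columns:
        raise ValueError("events must be labeled (run assign_subsets first)")
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must be in [0, 1)")
    nk = labeled[labeled["subset"] == "NK"]
    if len(nk) < min_nk:
        raise ValueError(
            f"only {len(nk)} NK events (minimum {min_nk}); the internal "
            "positive control is unreliable — supply manual gates instead"
        )
    return dataclasses.replace(
        gates,
        lamp1_gate=float(
            np.quantile(nk["LAMP1"].to_numpy(), quantile, method="lower")
        ),
        perforin_gate=float(
            np.quantile(nk["PERFORIN"].to_numpy(), quantile, method="lower")
        ),
        lamp1_gate_source="nk_anchored",
    )


def affected_fractions(
    labeled: pd.DataFrame, gates: GateSet, sample_id: str = "sample"
) -> SubsetReport:
    """Per-subset percentage of affected (LAMP-1+ perforin-) events.

    Subsets with zero events report ``pct_affected`` as missing (``None``),
    never as 0.  The NK row is included for completeness but flagged as the
    control population via ``control_population``.
    """
    _require_channels(labeled, ("LAMP1", "PERFORIN"))
    if "subset" not in labeled.columns:
        raise ValueError("events must be labeled (run assign_subsets first)")
    if not (math.isfinite(gates.lamp1_gate) and math.isfinite(gates.perforin_gate)):
        raise ValueError("LAMP-1/perforin gates not finalized")
    affected = (labeled["LAMP1"].to_numpy() >= gates.lamp1_gate) & (
        labeled["PERFORIN"].to_numpy() < gates.perforin_gate
    )
    report = SubsetReport(sample_id=sample_id)
    for name in LYMPHOCYTE_SUBSETS:
        m = (labeled["subset"] == name).to_numpy()
        n = int(m.sum())
        n_aff = int((affected & m).sum())
        report.subsets[name] = {
            "n_events": n,
            "n_affected": n_aff,
            "pct_affected": (100.0 * n_aff / n) if n > 0 else None,
        }
    return report
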