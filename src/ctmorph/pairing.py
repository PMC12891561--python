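"""Homolog pairing calls, conformation classes, and replicate summaries.

A nucleus is called *paired* for a given target (whole-chromosome, arm, or
centromeric probe) when the two FISH signals lie within 0.8 µm of each other
in 3D, or when only one signal is present (merged homologs).  Nuclei with
zero or more than two signals are *ambiguous* and excluded from percentages.
The same rule applies at every genomic scale; arm and centromere calls for one
chromosome combine into a conformation class (both/one/no arms paired ×
centromere paired/unpaired).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: 3D distance threshold (µm) for calling two homolog signals paired.
DEFAULT_PAIRING_THRESHOLD_UM = 0.8


@dataclass
class PairingCall:
    """Paired/unpaired decision for one nucleus × target."""

    nucleus_id: int
    target: str
    n_signals: int
    min_distance_um: float | None
    status: str  # paired | unpaired | ambiguous
    basis: str | None  # single_signal | distance | None


@dataclass
class ConformationClass:
    """Cross of arm pairing state and centromere pairing state."""

    nucleus_id: int
    chromosome: str
    arm_state: str  # both_arms_paired | one_arm_paired | no_arms_paired
    centromere_state: str  # cen_paired | cen_unpaired
    class_label: str

    @property
    def ambiguous(self) -> bool:
        return self.class_label == "ambiguous"


@dataclass
class PairingSummary:
    """Replicate-aggregated pairing percentage for one target."""

    target: str
    replicate_percents: dict
    mean_percent: float
    sd_percent: float | None
    total_nuclei: int
    n_replicates: int
    reportable: bool


def _euclidean_um(c1, c2) -> float:
    return math.dist(tuple(c1), tuple(c2))


def call_pairing(signals, *, threshold_um=DEFAULT_PAIRING_THRESHOLD_UM,
                 nucleus_id=None, target=None) -> PairingCall:
    """Call pairing for the signals of one nucleus × target.

    ``signals`` is a sequence of objects with ``centroid_um`` (and optionally
    ``nucleus_id`` / ``channel``), or a sequence of raw (z, y, x) µm tuples.
    The threshold comparison is inclusive: a distance of exactly
    ``threshold_um`` is paired.
    """
    centroids = []
    for s in signals:
        c = getattr(s, "centroid_um", s)
        sid = getattr(s, "nucleus_id", None)
        tgt = getattr(s, "channel", None)
        if sid is not None:
            if nucleus_id is None:
                nucleus_id = sid
            elif sid != nucleus_id:
                raise ValueError(
                    f"signals from multiple nuclei: {sid} vs {nucleus_id}")
        if tgt is not None:
            if target is None:
                target = tgt
            elif tgt != target:
                raise ValueError(
                    f"signals from multiple targets: {tgt} vs {target}")
        centroids.append(tuple(float(x) for x in c))
    nucleus_id = -1 if nucleus_id is None else nucleus_id
    target = "" if target is None else target

    n = len(centroids)
    if n == 0:
        return PairingCall(nucleus_id, target, 0, None, "ambiguous", None)
    if n == 1:
        return PairingCall(nucleus_id, target, 1, None, "paired",
                           "single_signal")
    dists = [_euclidean_um(centroids[i], centroids[j])
             for i in range(n) for j in range(i + 1, n)]
    dmin = min(dists)
    if n == 2:
        status = "paired" if dmin <= threshold_um else "unpaired"
        return PairingCall(nucleus_id, target, 2, dmin, status, "distance")
    return PairingCall(nucleus_id, target, n, dmin, "ambiguous", None)


_ARM_STATES = {2: "both_arms_paired", 1: "one_arm_paired", 0: "no_arms_paired"}


def classify_conformation(left_arm: PairingCall, right_arm: PairingCall,
                          centromere: PairingCall,
                          chromosome: str = "") -> ConformationClass:
    """Combine two arm calls and a centromere call into one of 6 classes."""
    calls = (left_arm, right_arm, centromere)
    nuclei = {c.nucleus_id for c in calls}
    if len(nuclei) != 1:
        raise ValueError(f"calls span multiple nuclei: {sorted(nuclei)}")
    nucleus_id = calls[0].nucleus_id
    if any(c.status == "ambiguous" for c in calls):
        return ConformationClass(nucleus_id, chromosome, "ambiguous",
                                 "ambiguous", "ambiguous")
    n_arms = sum(c.status == "paired" for c in (left_arm, right_arm))
    arm_state = _ARM_STATES[n_arms]
    cen_state = ("cen_paired" if centromere.status == "paired"
                 else "cen_unpaired")
    return ConformationClass(nucleus_id, chromosome, arm_state, cen_state,
                             f"{arm_state}/{cen_state}")


def conformation_percentages(classes) -> pd.Series:
    """Percent of (non-ambiguous) nuclei in each of the 6 conformation classes."""
    labels = [c.class_label for c in classes if not c.ambiguous]
    if not labels:
        return pd.Series(dtype=float)
    counts = pd.Series(labels).value_counts()
    return 100.0 * counts / counts.sum()


def aggregate_pairing(calls, *, min_nuclei=300, min_replicates=3,
                      target=None) -> PairingSummary:
    """Aggregate PairingCalls (each tagged with a replicate id) per target.

    ``calls`` is a sequence of ``(replicate_id, PairingCall)`` pairs or a
    DataFrame with columns ``replicate``, ``status`` (and ``target``).
    Ambiguous calls are excluded; replicates with no scorable calls are
    dropped with the count noted.  The mean and the standard deviation (ddof=1)
    are taken across replicate percentages, mirroring per-embryo error bars;
    the summary is flagged non-reportable when the total nucleus count or the
    replicate count falls below the configured minimum.
    """
    if isinstance(calls, pd.DataFrame):
        df = calls.copy()
    else:
        rows = [{"replicate": rep, "status": call.status,
                 "target": call.target} for rep, call in calls]
        df = pd.DataFrame(rows, columns=["replicate", "status", "target"])
    if target is not None and "target" in df.columns:
        df = df[df["target"] == target]
    elif target is None:
        targets = df["target"].unique() if "target" in df.columns else [""]
        target = targets[0] if len(targets) else ""
        if len(targets) > 1:
            raise ValueError(
                f"multiple targets present {list(targets)}; pass target=")

    scorable = df[df["status"].isin(["paired", "unpaired"])]
    percents: dict = {}
    total = 0
    for rep, grp in scorable.groupby("replicate"):
        n = len(grp)
        if n == 0:
            continue
        percents[rep] = 100.0 * (grp["status"] == "paired").mean()
        total += n
    n_reps = len(percents)
    if n_reps == 0:
        return PairingSummary(target, {}, float("nan"), None, 0, 0, False)
    vals = np.array(list(percents.values()), dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n_reps > 1 else None
    reportable = (total >= min_nuclei) and (n_reps >= min_replicates)
    return PairingSummary(target, percents, mean, sd, total, n_reps,
                          reportable)


def calls_to_frame(calls, replicate=None) -> pd.DataFrame:
    """Tidy DataFrame of PairingCalls (optionally tagged with a replicate id)."""
    rows = []
    for c in calls:
        rows.append({
            "nucleus_id": c.nucleus_id, "target": c.target,
            "n_signals": c.n_signals, "min_distance_um": c.min_distance_um,
            "status": c.status, "basis": c.basis, "replicate": replicate})
    cols = ["nucleus_id", "target", "n_signals", "min_distance_um", "status",
            "basis", "replicate"]
    return pd.DataFrame(rows, columns=cols)
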