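"""Enumeration and execution of the matching/non-matching comparison design.

The study compares every participant's antemortem (AM) scan against their own
postmortem (PM) scan (matching pairs, i vs i) and against every other
participant's PM scan (non-matching pairs, i vs j, i<j), per arch, for each
segmentation method, with replicate / session / operator structure layered on
top.  Replicates, sessions and operators perturb only the operator-variability
model (the slicing-plane jitter stream): the underlying clouds and ICP
subsampling for a pairing are held fixed, so replicate scatter isolates the
segmentation step, which is the quantity the standard-deviation analysis
summarizes.

Every cell's randomness derives from a stable hash of its coordinates plus
the design seed, so cells are independent, replayable in isolation, and the
results are invariant to execution order.
"""

from __future__ import annotations

import hashlib
import logging
import sys
import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .mesh_io import sample_surface
from .records import CSV_COLUMNS, ComparisonRecord
from .rigid_registration import ICPParams
from .segmentation import SegmentationMethod, SegmentationParams, compare_pair
from .synthetic_dentition import CohortScan

__all__ = [
    "StudyDesign",
    "enumerate_pairings",
    "run_study",
    "summarize_groups",
    "records_to_csv",
]

log = logging.getLogger("odontomatch")

ALL_METHODS = tuple(SegmentationMethod)


@dataclass
class StudyDesign:
    """Multiplicities of the comparison study.

    Defaults mirror the reference design: three replicates per cell, two
    sessions (the second a month later), two operators.
    """

    methods: tuple = ALL_METHODS
    replicates_per_cell: int = 3
    sessions: int = 2
    operators: int = 2
    seed: int = 0

    def __post_init__(self):
        self.methods = tuple(SegmentationMethod.parse(m) for m in self.methods)
        if not self.methods:
            raise ValueError("methods must be non-empty")
        if min(self.replicates_per_cell, self.sessions, self.operators) < 1:
            raise ValueError("replicates, sessions and operators must be >= 1")


def _stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary cell coordinates."""
    h = hashlib.blake2s("|".join(str(p) for p in parts).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") & 0x7FFFFFFF


def enumerate_pairings(cohort: list[CohortScan]):
    """All AM-vs-PM pairings of a cohort, partitioned by identity.

    Per arch: one matching pairing per participant (AM_i vs PM_i) and one
    unordered non-matching pairing per participant pair (AM_i vs PM_j, i<j).
    Slot ``a`` is always the AM side, slot ``b`` the PM side.
    """
    participants = sorted({s.participant_id for s in cohort})
    arches = sorted({s.arch for s in cohort})
    if len(participants) < 2:
        raise ValueError("need at least 2 participants")
    pairings = []
    for arch in arches:
        for p in participants:
            pairings.append((p, p, arch, True))
        for i, p in enumerate(participants):
            for q in participants[i + 1:]:
                pairings.append((p, q, arch, False))
    return pairings


def _scan_lookup(cohort):
    lut = {}
    for s in cohort:
        key = (s.participant_id, s.arch, s.capture)
        if key in lut:
            raise ValueError(f"duplicate scan {key} in cohort")
        lut[key] = s
    return lut


def run_study(cohort: list[CohortScan], design: StudyDesign,
              sp: SegmentationParams | None = None,
              icp: ICPParams | None = None,
              cloud_points: int = 40000,
              progress: bool = False) -> pd.DataFrame:
    """Run every comparison cell of the design and return the record table.

    Each scan is sampled once into a point cloud (seed derived from the scan
    identity and the design seed).  A cell failure is recorded as an error
    row; the run continues.  Deterministic: rerunning with the same seeds
    reproduces the table exactly (timestamps excluded from the CSV).
    """
    sp = sp or SegmentationParams()
    icp = icp or ICPParams()
    lut = _scan_lookup(cohort)
    clouds = {}
    for key, scan in lut.items():
        cseed = _stable_seed(design.seed, "cloud", *key)
        clouds[key] = sample_surface(scan.mesh, cloud_points, cseed)

    pairings = enumerate_pairings(cohort)
    rows = []
    n_cells = (len(pairings) * len(design.methods) * design.replicates_per_cell
               * design.sessions * design.operators)
    done = 0
    for (a, b, arch, is_match) in pairings:
        am_cloud = clouds[(a, arch, "AM")]
        pm_cloud = clouds[(b, arch, "PM")]
        for method in design.methods:
            icp_cell = replace(icp, seed=_stable_seed(design.seed, "icp", a, b,
                                                      arch, method.short))
            for operator in range(1, design.operators + 1):
                for session in range(1, design.sessions + 1):
                    for rep in range(1, design.replicates_per_cell + 1):
                        jseed = _stable_seed(design.seed, "jitter", a, b, arch,
                                             method.short, operator, session, rep)
                        sp_cell = replace(sp, seed=jseed)
                        meta = dict(participant_a=a, participant_b=b, arch=arch,
                                    is_match=is_match, replicate=rep,
                                    session=session, operator=operator)
                        try:
                            rec = compare_pair(am_cloud, pm_cloud, method,
                                               sp_cell, icp_cell, meta)
                        except Exception as exc:
                            rec = ComparisonRecord(
                                participant_a=a, participant_b=b, arch=arch,
                                method=method.short, replicate=rep,
                                session=session, operator=operator,
                                is_match=is_match, rms=float("nan"),
                                timestamp=time.time(), error=str(exc))
                        rows.append(rec.to_row())
                        done += 1
                        if progress and (done % 20 == 0 or done == n_cells):
                            print(f"\r  {done}/{n_cells} comparisons",
                                  end="", file=sys.stderr, flush=True)
    if progress:
        print(file=sys.stderr)
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def records_to_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def summarize_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Group means and replicate standard deviations of the RMS.

    The SD is computed over replicate RMS values within each pairing cell
    (participant pair × arch × method × operator × session), then averaged
    across pairings within each (method × is_match × operator) group.  A cell
    with fewer than two replicates yields a missing SD, never zero.
    """
    if table.empty:
        raise ValueError("empty results table")
    ok = table[table["error"].isna()] if "error" in table else table
    cell_keys = ["participant_a", "participant_b", "arch", "method",
                 "operator", "session"]
    cell_sd = (ok.groupby(cell_keys + ["is_match"])["rms"]
                 .agg(sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
                      n="size")
                 .reset_index())
    group_keys = ["method", "is_match", "operator"]
    means = ok.groupby(group_keys)["rms"].agg(mean_rms="mean", n="size")
    sds = cell_sd.groupby(group_keys)["sd"].mean().rename("mean_replicate_sd")
    out = means.join(sds).reset_index()
    return out
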