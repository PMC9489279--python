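"""Susceptibility calling from qPCR Ct data, and transmission scoring.

Susceptibility is decided against a benchmark-derived Ct threshold.  Each
experimental block carries control and benchmark samples:

========== =====================================================
role        description
========== =====================================================
control1    negative control (native host exposed to water)
control2    positive control, moderately susceptible native strain
control3    positive control, highly susceptible native strain
benchmark4  virus on a worm-free plate, carried through washing and
            extraction: exposure virus that survives the protocol
benchmark5  virus diluted directly into the extraction volume: the
            maximum virus possible without replication
========== =====================================================

Because Ct is inversely related to template amount, "more virus" means a
*lower* Ct.  The default threshold is one within-strain standard deviation
of Ct more virus than the most virus ever seen in benchmark 4:
``tau = min(detected benchmark-4 Ct) - sigma_w``, and a strain is called
susceptible when at least one replicate population has ``Ct < tau``
(strictly).  Benchmark 5 can be used instead as a deliberately conservative
alternative.

Transmission across serial passages is summarised by an ordinal 0-3 score:
0 = no detection in the exposure population; 1 = detected at exposure but
not at passage 1; 2 = detected at passage 1 but lost on or before passage
5; 3 = still detectable at passage 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ROLES",
    "CtTable",
    "SusceptibilityThreshold",
    "SusceptibilityCall",
    "PassageTrajectory",
    "TransmissionScore",
    "load_ct_table",
    "write_ct_table",
    "within_strain_sd",
    "derive_threshold",
    "call_susceptibility",
    "calls_to_frame",
    "score_transmission",
    "load_trajectories",
    "write_trajectories",
    "summarize_benchmarks",
]

ROLES = (
    "experimental",
    "control1_neg",
    "control2_N2",
    "control3_JU1580",
    "benchmark4",
    "benchmark5",
)

#: Strings in the ct column that denote a non-detection.
UNDETECTED_TOKENS = {"", "na", "nd", "nan", "undetected"}

CT_COLUMNS = ["strain", "species", "block", "replicate", "role", "ct"]


class CtTableError(ValueError):
    """Invalid Ct table contents."""


@dataclass
class CtTable:
    """Long-format qPCR records; ``ct`` is NaN where virus was undetected.

    ``undetected_ct`` is the Ct imputed for non-detections wherever an
    operation needs a numeric value (the qPCR run length, 40 cycles, by
    default).
    """

    records: pd.DataFrame
    undetected_ct: float = 40.0

    def __post_init__(self):
        missing = [c for c in CT_COLUMNS if c not in self.records.columns]
        if missing:
            raise CtTableError(f"Ct table missing columns: {missing}")
        bad_roles = sorted(set(self.records["role"]) - set(ROLES))
        if bad_roles:
            raise CtTableError(f"unknown roles {bad_roles}; allowed: {list(ROLES)}")
        ct = self.records["ct"]
        detected = ct.dropna()
        out = detected[(detected <= 0) | (detected > 40)]
        if len(out):
            rows = list(out.index[:5])
            raise CtTableError(
                f"Ct values outside (0, 40] at rows {rows}: {out.head().tolist()}"
            )
        keys = self.records[["strain", "block", "replicate", "role"]]
        dup = keys.duplicated()
        if dup.any():
            raise CtTableError(
                f"duplicate (strain, block, replicate, role) keys at rows "
                f"{list(self.records.index[dup][:5])}"
            )
        exp_blocks = set(self.records.loc[self.records.role == "experimental", "block"])
        b4_blocks = set(self.records.loc[self.records.role == "benchmark4", "block"])
        orphan = sorted(exp_blocks - b4_blocks)
        if orphan:
            logger.warning(
                "blocks %s contain experimental records but no benchmark-4 records",
                orphan,
            )

    @property
    def experimental(self) -> pd.DataFrame:
        return self.records[self.records.role == "experimental"]

    def imputed_ct(self, frame: pd.DataFrame | None = None) -> pd.Series:
        """Ct with non-detections imputed to ``undetected_ct`` (logged)."""
        frame = self.records if frame is None else frame
        n_missing = int(frame["ct"].isna().sum())
        if n_missing:
            logger.info(
                "imputing Ct = %g for %d undetected samples", self.undetected_ct, n_missing
            )
        return frame["ct"].fillna(self.undetected_ct)


def _parse_ct_value(value):
    if value is None:
        return np.nan
    text = str(value).strip().lower()
    if text in UNDETECTED_TOKENS:
        return np.nan
    return float(value)


def load_ct_table(path, undetected_ct: float = 40.0) -> CtTable:
    """Read a comma- or tab-separated Ct table.

    Required header columns: strain, species, block, replicate, role, ct.
    ``NA``/``ND``/empty in the ct column denote non-detection.
    """
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in CT_COLUMNS if c not in frame.columns]
    if missing:
        raise CtTableError(f"{path}: missing columns {missing}")
    try:
        frame["ct"] = frame["ct"].map(_parse_ct_value)
    except ValueError as exc:
        raise CtTableError(f"{path}: unparseable ct value ({exc})") from exc
    frame["block"] = frame["block"].astype(int)
    frame["replicate"] = frame["replicate"].astype(int)
    frame = frame.reset_index(drop=True)
    return CtTable(records=frame, undetected_ct=undetected_ct)


def write_ct_table(table: CtTable, path) -> None:
    out = table.records.copy()
    out["ct"] = out["ct"].map(lambda v: "ND" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


def within_strain_sd(table: CtTable) -> float:
    """Pooled within-strain standard deviation of experimental Cts.

    Per-strain sample variance (ddof=1) of replicate Cts with non-detections
    imputed, averaged over strains, square-rooted.  Strains with fewer than
    two replicates carry no variance information and are excluded (logged).
    """
    exp = table.experimental.copy()
    if exp.empty:
        raise CtTableError("no experimental records")
    exp["ct_num"] = table.imputed_ct(exp)
    counts = exp.groupby("strain")["ct_num"].count()
    usable = counts[counts >= 2].index
    skipped = sorted(set(counts.index) - set(usable))
    if skipped:
        logger.info("excluding %d strains with <2 replicates from sigma_w: %s",
                    len(skipped), skipped[:10])
    if len(usable) == 0:
        raise CtTableError("no strain has >= 2 replicates; cannot estimate sigma_w")
    variances = (
        exp[exp.strain.isin(usable)].groupby("strain")["ct_num"].var(ddof=1)
    )
    return float(np.sqrt(variances.mean()))


@dataclass
class SusceptibilityThreshold:
    """Benchmark-derived infection threshold ``tau`` on the Ct scale."""

    benchmark_max_virus_ct: float  # minimum detected Ct among benchmark wells
    within_strain_sd: float
    threshold: float
    benchmark: int = 4

    def __post_init__(self):
        if not np.isfinite(self.threshold) or self.threshold <= 0:
            raise CtTableError(f"non-positive threshold {self.threshold}")
        if self.threshold >= self.benchmark_max_virus_ct and self.within_strain_sd > 0:
            raise CtTableError("threshold must lie below the benchmark minimum Ct")


def derive_threshold(
    table: CtTable, sigma_w: float, benchmark: int = 4
) -> SusceptibilityThreshold:
    """Threshold = (minimum detected benchmark Ct) - sigma_w.

    The minimum detected Ct is the *most* virus ever observed in the
    benchmark wells; subtracting one within-strain standard deviation
    demands one sd more virus than that carry-over level.  With
    ``benchmark=5`` the conservative no-replication benchmark is used
    instead (and sigma_w is still subtracted the same way).
    """
    role = f"benchmark{benchmark}"
    if role not in ROLES:
        raise CtTableError(f"benchmark must be 4 or 5, got {benchmark}")
    rows = table.records[table.records.role == role]
    detected = rows["ct"].dropna()
    if detected.empty:
        raise CtTableError(f"no detected {role} record; cannot derive threshold")
    most_virus = float(detected.min())
    return SusceptibilityThreshold(
        benchmark_max_virus_ct=most_virus,
        within_strain_sd=float(sigma_w),
        threshold=most_virus - float(sigma_w),
        benchmark=benchmark,
    )


@dataclass
class SusceptibilityCall:
    strain: str
    species: str
    n_replicates: int
    n_infected: int
    susceptible: bool


def call_susceptibility(table: CtTable, threshold) -> list[SusceptibilityCall]:
    """Per-strain infection calls: replicate infected iff ``Ct < tau`` strictly.

    A strain is susceptible when at least one replicate is infected.
    Controls and benchmarks never enter the calls.
    """
    tau = threshold.threshold if isinstance(threshold, SusceptibilityThreshold) else float(threshold)
    exp = table.experimental
    calls = []
    for (strain, species), group in exp.groupby(["strain", "species"], sort=False):
        ct = group["ct"]
        n_infected = int((ct < tau).sum())  # NaN (undetected) compares False
        calls.append(
            SusceptibilityCall(
                strain=strain,
                species=species,
                n_replicates=len(group),
                n_infected=n_infected,
                susceptible=n_infected >= 1,
            )
        )
    return calls


def calls_to_frame(calls: list[SusceptibilityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain": c.strain,
                "species": c.species,
                "n_replicates": c.n_replicates,
                "n_infected": c.n_infected,
                "susceptible": c.susceptible,
            }
            for c in calls
        ]
    )


@dataclass
class PassageTrajectory:
    """Virus detection across serial passages of one replicate line.

    ``detections[0]`` refers to the primary exposure population (passage 0);
    later entries to passages 1..5.  A line whose last recorded passage is a
    non-detection terminated early by loss and counts as undetected
    thereafter.
    """

    line_id: str
    strain: str
    detections: list[bool]
    passage0_ct: float | None = None
    species: str | None = None

    def __post_init__(self):
        if len(self.detections) == 0:
            raise ValueError(f"line {self.line_id}: empty detection sequence")
        if len(self.detections) > 6:
            raise ValueError(f"line {self.line_id}: more than 6 passages recorded")


@dataclass
class TransmissionScore:
    line_id: str
    strain: str
    score: int


MAX_PASSAGE = 5


def score_transmission(traj: PassageTrajectory) -> TransmissionScore:
    """Ordinal 0-3 transmission score of a passage line.

    0: undetected in the exposure population.  1: detected at exposure but
    not at passage 1.  2: detected at passage 1 but lost on or before
    passage 5.  3: still detectable at passage 5.  Lines that stopped early
    because virus became undetectable are padded with non-detections; a line
    still detected at its last recorded passage but shorter than six entries
    is ambiguous (score 2 vs 3) and rejected.
    """
    d = list(traj.detections)
    if len(d) < MAX_PASSAGE + 1:
        if d[-1]:
            raise ValueError(
                f"line {traj.line_id}: truncated trajectory (detected at its last "
                f"recorded passage {len(d) - 1} but passage {MAX_PASSAGE} status is "
                "needed to score)"
            )
        d = d + [False] * (MAX_PASSAGE + 1 - len(d))
    if not d[0]:
        score = 0
    elif not d[1]:
        score = 1
    elif d[MAX_PASSAGE]:
        score = 3
    else:
        score = 2
    return TransmissionScore(line_id=traj.line_id, strain=traj.strain, score=score)


TRAJECTORY_COLUMNS = ["line_id", "strain", "species", "passage", "detected", "passage0_ct"]


def load_trajectories(path) -> list[PassageTrajectory]:
    """Read long-format trajectories: one row per (line, passage)."""
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in ("line_id", "strain", "passage", "detected") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    frame["passage"] = frame["passage"].astype(int)
    trajectories = []
    for line_id, group in frame.groupby("line_id", sort=False):
        group = group.sort_values("passage")
        expected = list(range(len(group)))
        if list(group["passage"]) != expected:
            raise ValueError(
                f"line {line_id}: passages must be contiguous from 0, got "
                f"{list(group['passage'])}"
            )
        detections = [str(v).strip().lower() in {"1", "true", "yes", "t"} for v in group["detected"]]
        ct0 = None
        if "passage0_ct" in group.columns:
            ct0 = _parse_ct_value(group["passage0_ct"].iloc[0])
            ct0 = None if np.isnan(ct0) else float(ct0)
        species = group["species"].iloc[0] if "species" in group.columns else None
        trajectories.append(
            PassageTrajectory(
                line_id=str(line_id),
                strain=str(group["strain"].iloc[0]),
                detections=detections,
                passage0_ct=ct0,
                species=species,
            )
        )
    return trajectories


def write_trajectories(trajectories: list[PassageTrajectory], path) -> None:
    rows = []
    for traj in trajectories:
        for passage, detected in enumerate(traj.detections):
            rows.append(
                {
                    "line_id": traj.line_id,
                    "strain": traj.strain,
                    "species": traj.species or "",
                    "passage": passage,
                    "detected": int(detected),
                    "passage0_ct": "ND" if traj.passage0_ct is None else f"{traj.passage0_ct:.6g}",
                }
            )
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, sep="\t", index=False)


def summarize_benchmarks(table: CtTable) -> pd.DataFrame:
    """Mean/sd/n of detected Cts per control/benchmark role."""
    rows = []
    for role in ROLES:
        if role == "experimental":
            continue
        sub = table.records[table.records.role == role]
        if sub.empty:
            logger.warning("role %s absent from table; omitted from summary", role)
            continue
        detected = sub["ct"].dropna()
        rows.append(
            {
                "role": role,
                "n_detected": len(detected),
                "n_total": len(sub),
                "mean_ct": float(detected.mean()) if len(detected) else np.nan,
                "sd_ct": float(detected.std(ddof=1)) if len(detected) >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("role")
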