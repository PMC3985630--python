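"""Single-molecule fluorophore traces and their on-disk TSV dialect.

A trace is one combed DNA molecule reduced to the 1D positions (nm, origin
at one molecule end) of its localized fluorophore labels.  Simulated traces
additionally carry per-label ground truth: whether the label came from a
real recognition site (and which) or is a false positive, plus the
molecule's true origin interval and combing orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LabelTruth",
    "MoleculeGroundTruth",
    "MoleculeTrace",
    "write_traces_tsv",
    "read_traces_tsv",
    "write_ground_truth_tsv",
    "read_ground_truth_tsv",
]

TRUE_SITE = "true_site"
FALSE_POSITIVE = "false_positive"


@dataclass(frozen=True)
class LabelTruth:
    """Origin of one localized label (simulation only)."""

    label_class: str  # 'true_site' or 'false_positive'
    site_index: int  # index into the source SiteMap records; -1 for FPs


@dataclass
class MoleculeGroundTruth:
    origin_start_bp: int
    origin_end_bp: int
    orientation: str  # 'forward' or 'reverse'
    stretch: float  # drawn combing stretch factor for this molecule
    labels: list[LabelTruth] = field(default_factory=list)


@dataclass
class MoleculeTrace:
    molecule_id: str
    positions_nm: np.ndarray  # sorted, within [0, length_nm]
    length_nm: float
    photons: np.ndarray | None = None
    precision_nm: np.ndarray | None = None
    ground_truth: MoleculeGroundTruth | None = None

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        if self.positions_nm.ndim != 1:
            raise ValueError("positions_nm must be 1-D")
        if np.any(np.diff(self.positions_nm) < 0):
            raise ValueError("positions_nm must be sorted")
        if self.positions_nm.size and (
            self.positions_nm[0] < 0 or self.positions_nm[-1] > self.length_nm + 1e-9
        ):
            raise ValueError("positions outside [0, length_nm]")
        if self.ground_truth is not None and len(self.ground_truth.labels) != self.n_labels:
            raise ValueError("one ground-truth record per label required")

    @property
    def n_labels(self) -> int:
        return int(self.positions_nm.size)


def write_traces_tsv(traces: Sequence[MoleculeTrace], path: str | Path) -> None:
    """One row per label: molecule_id, position_nm, photons, precision_nm.

    A '#molecule' comment line per molecule carries its measured extent,
    so label-free molecules survive a round trip.
    """
    with open(path, "w") as fh:
        fh.write("#molecule_id\tposition_nm\tphotons\tprecision_nm\n")
        for t in traces:
            fh.write(f"#molecule\t{t.molecule_id}\tlength_nm={t.length_nm:.4f}\n")
            for i in range(t.n_labels):
                ph = "" if t.photons is None else f"{t.photons[i]:.1f}"
                pr = "" if t.precision_nm is None else f"{t.precision_nm[i]:.3f}"
                fh.write(f"{t.molecule_id}\t{t.positions_nm[i]:.4f}\t{ph}\t{pr}\n")


def read_traces_tsv(path: str | Path) -> list[MoleculeTrace]:
    order: list[str] = []
    lengths: dict[str, float] = {}
    rows: dict[str, list[tuple[float, float | None, float | None]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#molecule\t"):
                _, mol_id, meta = line.split("\t")
                lengths[mol_id] = float(meta.split("=", 1)[1])
                order.append(mol_id)
                rows.setdefault(mol_id, [])
                continue
            if line.startswith("#"):
                continue
            mol_id, pos, ph, pr = line.split("\t")
            if mol_id not in lengths:
                raise ValueError(f"{path}: label row before '#molecule' header for {mol_id}")
            rows[mol_id].append(
                (float(pos), float(ph) if ph else None, float(pr) if pr else None)
            )
    traces = []
    for mol_id in order:
        rr = sorted(rows[mol_id])
        pos = np.array([r[0] for r in rr])
        photons = None if any(r[1] is None for r in rr) else np.array([r[1] for r in rr])
        prec = None if any(r[2] is None for r in rr) else np.array([r[2] for r in rr])
        traces.append(
            MoleculeTrace(mol_id, pos, lengths[mol_id], photons=photons, precision_nm=prec)
        )
    return traces


def write_ground_truth_tsv(traces: Sequence[MoleculeTrace], path: str | Path) -> None:
    cols = (
        "molecule_id\tlabel_index\tclass\tsite_index\t"
        "origin_start_bp\torigin_end_bp\torientation\tstretch\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for t in traces:
            gt = t.ground_truth
            if gt is None:
                raise ValueError(f"trace {t.molecule_id} has no ground truth")
            for i, lab in enumerate(gt.labels):
                fh.write(
                    f"{t.molecule_id}\t{i}\t{lab.label_class}\t{lab.site_index}\t"
                    f"{gt.origin_start_bp}\t{gt.origin_end_bp}\t{gt.orientation}\t"
                    f"{gt.stretch:.6f}\n"
                )


def read_ground_truth_tsv(path: str | Path) -> dict[str, MoleculeGroundTruth]:
    out: dict[str, MoleculeGroundTruth] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("molecule_id"):
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) != 8:
                continue
            mol_id, idx, cls, site_idx, o0, o1, orient, stretch = f
            gt = out.setdefault(
                mol_id,
                MoleculeGroundTruth(int(o0), int(o1), orient, float(stretch)),
            )
            assert int(idx) == len(gt.labels)
            gt.labels.append(LabelTruth(cls, int(site_idx)))
    return out
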