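"""Synthetic molecular-combing and labelling simulator.

Generates single-molecule fluorophore traces with full ground truth,
emulating the statistical properties of methyltransferase-directed optical
mapping data:

* copper-mediated fragmentation of the DNA during the click-labelling
  reaction (Poisson break count per molecule; calibration presets expressed
  as the fraction of molecules surviving intact),
* per-site Bernoulli labelling at ~70% efficiency,
* false-positive labels as a uniform Poisson process along the molecule,
  with a default rate tuned so roughly one third of all localized labels
  are false positives,
* molecular-combing stretch drawn per molecule from a truncated normal
  around 1.59 x the B-DNA crystallographic length (0.34 nm/bp),
* Gaussian localization noise (default sd 10 nm) and random combing
  orientation.

All randomness flows from one integer seed through named substreams, so a
fixed seed reproduces the dataset byte-for-byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeSequence, SiteMap
from .traces import (
    FALSE_POSITIVE,
    TRUE_SITE,
    LabelTruth,
    MoleculeGroundTruth,
    MoleculeTrace,
)

__all__ = [
    "RISE_NM_PER_BP",
    "CombingModel",
    "FragmentationParams",
    "FRAGMENTATION_PRESETS",
    "LabellingParams",
    "SimulationParams",
    "stage_rng",
    "fragment_molecules",
    "project_to_nm",
    "default_fp_rate_per_bp",
    "simulate_dataset",
]

#: B-DNA crystallographic rise, nm per base pair.
RISE_NM_PER_BP = 0.34


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible substream for a named pipeline stage."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(stage.encode())])


@dataclass(frozen=True)
class CombingModel:
    """Molecular-combing stretch model: nm per bp = rise x stretch."""

    stretch_mean: float = 1.59
    stretch_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.stretch_mean <= 1:
            raise ValueError("stretch_mean must exceed 1 (combing over-stretches)")
        if self.stretch_sd < 0:
            raise ValueError("stretch_sd must be >= 0")

    def draw_stretch(self, rng: np.random.Generator) -> float:
        """One per-molecule stretch draw, truncated at +-3 sd."""
        if self.stretch_sd == 0:
            return self.stretch_mean
        while True:
            s = rng.normal(self.stretch_mean, self.stretch_sd)
            if abs(s - self.stretch_mean) <= 3 * self.stretch_sd:
                return s

    def nm_per_bp(self, stretch: float | None = None) -> float:
        return RISE_NM_PER_BP * (self.stretch_mean if stretch is None else stretch)


@dataclass(frozen=True)
class FragmentationParams:
    """Poisson fragmentation: the intact fraction is exp(-mean_breaks)."""

    mean_breaks: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_breaks < 0:
            raise ValueError("mean_breaks must be >= 0")

    @classmethod
    def from_survival(cls, survival: float) -> "FragmentationParams":
        """Calibrate the break rate to a target intact-molecule fraction."""
        if not 0 < survival <= 1:
            raise ValueError("survival fraction must be in (0, 1]")
        return cls(mean_breaks=-float(np.log(survival)))


#: Click-reaction condition presets, calibrated to the observed fraction of
#: molecules protected from copper-mediated cleavage.
FRAGMENTATION_PRESETS: dict[str, FragmentationParams] = {
    "TBTA/40% DMSO": FragmentationParams.from_survival(0.20),
    "THPTA/20% DMSO": FragmentationParams.from_survival(0.33),
    "THPTA 10:1 excess": FragmentationParams.from_survival(0.80),
}


@dataclass(frozen=True)
class LabellingParams:
    """Labelling efficiency, false-positive rate and localization noise.

    ``fp_rate_per_bp`` of None means "derive at run time" so that the
    expected false-positive count is half the expected true-label count,
    i.e. FPs make up one third of all labels.
    """

    p_label: float = 0.70
    fp_rate_per_bp: float | None = None
    sigma_loc_nm: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_label <= 1:
            raise ValueError("p_label must be in [0, 1]")
        if self.fp_rate_per_bp is not None and self.fp_rate_per_bp < 0:
            raise ValueError("fp_rate_per_bp must be >= 0")
        if self.sigma_loc_nm < 0:
            raise ValueError("sigma_loc_nm must be >= 0")


@dataclass(frozen=True)
class SimulationParams:
    n_molecules: int = 14
    length_mode: str = "uniform"  # 'fixed' | 'uniform' | 'fragmentation'
    length_bp_range: tuple[int, int] = (23_000, 36_000)
    combing: CombingModel = field(default_factory=CombingModel)
    fragmentation: FragmentationParams = field(default_factory=FragmentationParams)
    labelling: LabellingParams = field(default_factory=LabellingParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.length_mode not in ("fixed", "uniform", "fragmentation"):
            raise ValueError(f"unknown length_mode {self.length_mode!r}")
        lo, hi = self.length_bp_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length_bp_range")


def fragment_molecules(
    length_bp: int,
    frag: FragmentationParams,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[list[tuple[int, int]]]:
    """Simulate copper-mediated cleavage of ``n`` molecules of ``length_bp``.

    Per molecule, a Poisson(mean_breaks) number of break points is drawn
    uniformly; the returned half-open bp intervals partition the molecule.
    """
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, "fragmentation")
    out = []
    for _ in range(n):
        k = rng.poisson(frag.mean_breaks)
        cuts = np.sort(rng.integers(1, length_bp, size=k)) if k else np.array([], dtype=int)
        bounds = np.concatenate(([0], np.unique(cuts), [length_bp])).astype(int)
        out.append([(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]) if b > a])
    return out


def project_to_nm(pos_bp, combing: CombingModel, stretch_draw: float):
    """bp coordinate along a combed molecule -> nm: pos x 0.34 x stretch."""
    pos_bp = np.asarray(pos_bp, dtype=float)
    if np.any(pos_bp < 0):
        raise ValueError("bp positions must be >= 0")
    return pos_bp * RISE_NM_PER_BP * stretch_draw


def default_fp_rate_per_bp(sitemap: SiteMap, p_label: float) -> float:
    """False-positive rate making E[FP] = 0.5 x E[true labels] (FPs ~ 1/3)."""
    site_density = sitemap.n_sites / sitemap.genome_length
    return 0.5 * p_label * site_density


def _sample_origin(
    genome_length: int, params: SimulationParams, rng: np.random.Generator
) -> tuple[int, int]:
    lo, hi = params.length_bp_range
    if params.length_mode == "fixed":
        length = min(lo, genome_length)
    elif params.length_mode == "uniform":
        length = int(rng.integers(lo, hi + 1))
        length = min(length, genome_length)
    else:  # fragmentation-driven: comb one random fragment of a broken genome
        frags = fragment_molecules(genome_length, params.fragmentation, 1, rng)[0]
        start, end = frags[int(rng.integers(len(frags)))]
        return start, end
    start = int(rng.integers(0, genome_length - length + 1))
    return start, start + length


def simulate_dataset(
    genome: GenomeSequence,
    sitemap: SiteMap,
    params: SimulationParams,
) -> list[MoleculeTrace]:
    """Simulate a combed, labelled, localized single-molecule dataset.

    Every trace carries per-label ground truth (site index or false
    positive), the molecule's true genome interval, orientation and stretch
    draw, so every downstream stage can be validated against the truth.
    """
    if sitemap.genome_length != genome.length or sitemap.genome_id != genome.id:
        raise ValueError(
            f"site map for {sitemap.genome_id!r}/{sitemap.genome_length} bp does not "
            f"match genome {genome.id!r}/{genome.length} bp"
        )
    lab = params.labelling
    fp_rate = (
        default_fp_rate_per_bp(sitemap, lab.p_label)
        if lab.fp_rate_per_bp is None
        else lab.fp_rate_per_bp
    )
    site_pos = np.asarray(sitemap.positions(), dtype=int)
    rng = stage_rng(params.seed, "simulate")

    traces = []
    for m in range(params.n_molecules):
        start, end = _sample_origin(genome.length, params, rng)
        if end - start > genome.length:
            raise ValueError("molecule interval longer than genome")
        stretch = params.combing.draw_stretch(rng)
        length_nm = float(project_to_nm(end - start, params.combing, stretch))

        in_span = np.flatnonzero((site_pos >= start) & (site_pos < end))
        keep = in_span[rng.random(in_span.size) < lab.p_label]
        true_bp = site_pos[keep] - start

        n_fp = rng.poisson(fp_rate * (end - start))
        fp_bp = rng.uniform(0, end - start, size=n_fp)

        pos_bp = np.concatenate([true_bp.astype(float), fp_bp])
        truth = [LabelTruth(TRUE_SITE, int(i)) for i in keep] + [
            LabelTruth(FALSE_POSITIVE, -1)
        ] * n_fp

        pos_nm = project_to_nm(pos_bp, params.combing, stretch)
        orientation = "forward" if rng.random() < 0.5 else "reverse"
        if orientation == "reverse":
            pos_nm = length_nm - pos_nm
        if lab.sigma_loc_nm > 0:
            pos_nm = pos_nm + rng.normal(0.0, lab.sigma_loc_nm, size=pos_nm.size)
        pos_nm = np.clip(pos_nm, 0.0, length_nm)

        order = np.argsort(pos_nm, kind="stable")
        gt = MoleculeGroundTruth(
            origin_start_bp=start,
            origin_end_bp=end,
            orientation=orientation,
            stretch=stretch,
            labels=[truth[i] for i in order],
        )
        traces.append(
            MoleculeTrace(
                molecule_id=f"mol{m:04d}",
                positions_nm=pos_nm[order],
                length_nm=length_nm,
                ground_truth=gt,
            )
        )
    return traces
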