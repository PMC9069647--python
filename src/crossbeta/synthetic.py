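"""Ground-truth synthetic structures: ideal fibrils and negative decoys.

The generator emulates the geometry that the detector targets: in-register
parallel beta-strand pairs at cross-beta spacing (4.8 A between stacked
strands, ~3.4 A rise per residue) carrying user-chosen sequences, so the
boundary prefix of every planted segment is known a priori.

Layout.  Chains are stacked pairwise as dimeric protofilaments; successive
protofilaments sit 25 A apart, outside the detection band, mirroring real
fibril architectures in which the protofilament interface is not an
in-register parallel contact.  Within a dimer the strand residues of the
two chains face each other at ``inter_strand_spacing``; all other residues
(the boundary coil) of the two chains converge to ~0.3 A apart.  That
convergence is what makes the planted segment *maximal*: extending a
detected window by one residue at either end adds a pair whose distance
falls below the 2 A floor, so detection recovers exactly the planted
boundaries and hence exactly the planted XXYYY prefix.  Coil residues are
additionally kept off the strand axis (>= 1 A) with a small zig-zag so no
coil stretch resembles a straight strand.

Noise.  ``noise_sd`` adds a smooth correlated Gaussian displacement field
along each chain (per-coordinate sd = noise_sd, correlation length ~3
residues), emulating ensemble/thermal variation.  Independent per-atom
noise would stretch consecutive C-alpha pseudo-bonds unphysically and sever
chains at the 4.5 A break heuristic; a correlated field perturbs positions
without tearing the backbone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import (
    NMR,
    ONE_TO_THREE,
    ChainModel,
    ResidueRecord,
    StructureModel,
    classify_method,
)

__all__ = ["SheetSpec", "generate_parallel_sheet", "generate_decoy",
           "ground_truth", "DECOY_KINDS"]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_COIL_GAP = 0.3  # inter-chain coil separation within a dimer, Angstrom
_PROTOFILAMENT_SPACING = 25.0
_ZIGZAG = 1.2  # coil off-axis zig-zag amplitude, Angstrom
_BOUNDARY_PULLBACK = 1.4  # coil x-shift toward the segment, Angstrom


@dataclass(frozen=True)
class SheetSpec:
    """Recipe for one synthetic parallel-sheet structure."""

    chain_sequence: str
    segment_start: int
    segment_length: int
    n_chains: int = 2
    inter_strand_spacing: float = 4.8
    rise_per_residue: float = 3.4
    twist_per_residue: float = 0.0  # degrees
    noise_sd: float = 0.0
    seed: int = 0
    n_models: int = 1
    entry_id: str = "SYNT"
    method_text: str = "SOLID-STATE NMR"

    def __post_init__(self) -> None:
        n = len(self.chain_sequence)
        if n == 0:
            raise ValueError("chain_sequence must be non-empty")
        bad = set(self.chain_sequence.upper()) - set(ONE_TO_THREE)
        if bad:
            raise ValueError(f"non-standard letters in sequence: {bad}")
        if self.segment_length < 3:
            raise ValueError("segment_length must be >= 3")
        if self.segment_start < 0 or self.segment_start + self.segment_length > n:
            raise ValueError("segment must lie within the sequence")
        if not 2 <= self.n_chains <= len(_CHAIN_IDS):
            raise ValueError("n_chains must be between 2 and 26")
        if not 2.0 < self.inter_strand_spacing <= 8.0:
            raise ValueError("inter_strand_spacing must be in (2, 8] A")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


def _smooth_noise(rng: np.random.Generator, n: int, sd: float,
                  corr: float = 3.0) -> np.ndarray:
    """Correlated Gaussian field, marginal per-coordinate sd = ``sd``."""
    if sd == 0.0:
        return np.zeros((n, 3))
    half = int(math.ceil(4 * corr))
    kernel = np.exp(-np.arange(-half, half + 1) ** 2 / (2 * corr ** 2))
    kernel = kernel / math.sqrt(float(np.sum(kernel ** 2)))
    raw = rng.normal(size=(n + 2 * half, 3))
    out = np.empty((n, 3))
    for axis in range(3):
        out[:, axis] = np.convolve(raw[:, axis], kernel, mode="valid")
    return out * sd


def _base_chain_coords(spec: SheetSpec) -> np.ndarray:
    """Coordinates of the reference (lower) chain of a dimer."""
    n = len(spec.chain_sequence)
    rise = spec.rise_per_residue
    start, L = spec.segment_start, spec.segment_length
    delta = (spec.inter_strand_spacing - _COIL_GAP) / 2.0
    coords = np.zeros((n, 3))
    for i in range(n):
        if start <= i < start + L:
            coords[i] = (i * rise, 0.0, 0.0)
        elif i < start:
            k = start - 1 - i  # 0 for the residue adjacent to the segment
            z = 0.0 if k == 0 else _ZIGZAG * (1 if k % 2 else -1)
            coords[i] = (i * rise + _BOUNDARY_PULLBACK, delta, z)
        else:
            k = i - (start + L)  # 0 for the residue adjacent to the segment
            z = 0.0 if k == 0 else _ZIGZAG * (1 if k % 2 else -1)
            coords[i] = (i * rise - _BOUNDARY_PULLBACK, delta, z)
    return coords


def _partner_offsets(spec: SheetSpec) -> np.ndarray:
    """Per-residue offset from the reference chain to its dimer partner."""
    n = len(spec.chain_sequence)
    start, L = spec.segment_start, spec.segment_length
    twist = math.radians(spec.twist_per_residue)
    offsets = np.zeros((n, 3))
    for i in range(n):
        d = spec.inter_strand_spacing if start <= i < start + L else _COIL_GAP
        theta = twist * i
        offsets[i] = (0.0, d * math.cos(theta), d * math.sin(theta))
    return offsets


def _make_chain(chain_id: str, sequence: str, coords: np.ndarray) -> ChainModel:
    residues = [
        ResidueRecord(
            chain_id=chain_id,
            author_seq_number=i + 1,
            insertion_code="",
            residue_name=ONE_TO_THREE[letter],
            one_letter=letter,
            ca_position=np.array(coords[i], dtype=float),
        )
        for i, letter in enumerate(sequence)
    ]
    return ChainModel(chain_id=chain_id, residues=residues)


def generate_parallel_sheet(spec: SheetSpec) -> StructureModel:
    """Deterministic synthetic fibril with planted parallel segments.

    Returns ``n_chains`` copies of the sequence as separate chains arranged
    in dimeric protofilaments (an odd trailing chain gets no partner and is
    never detected).  For a fixed seed the output is bit-reproducible.
    """
    seq = spec.chain_sequence.upper()
    n = len(seq)
    rng = np.random.default_rng(spec.seed)
    base = _base_chain_coords(spec)
    partner = _partner_offsets(spec)
    models: list[list[ChainModel]] = []
    for _ in range(spec.n_models):
        chains: list[ChainModel] = []
        for c in range(spec.n_chains):
            p, s = divmod(c, 2)
            coords = base.copy()
            if s == 1:
                coords = coords + partner
            coords[:, 1] += p * _PROTOFILAMENT_SPACING
            coords = coords + _smooth_noise(rng, n, spec.noise_sd)
            chains.append(_make_chain(_CHAIN_IDS[c], seq, coords))
        models.append(chains)
    return StructureModel(
        entry_id=spec.entry_id,
        method_class=classify_method(spec.method_text),
        models=models,
        raw_method=spec.method_text,
    )


def ground_truth(spec: SheetSpec) -> dict:
    """A-priori expectations for a generated sheet (sidecar content)."""
    seq = spec.chain_sequence.upper()
    start, L = spec.segment_start, spec.segment_length
    n_dimers = spec.n_chains // 2
    prefix = seq[start - 2:start + 3] if start >= 2 else None
    suffix_end = start + L
    suffix = (seq[suffix_end - 3:suffix_end + 2]
              if suffix_end + 2 <= len(seq) else None)
    chains_in_dimers = 2 * n_dimers
    return {
        "entry_id": spec.entry_id,
        "n_models": spec.n_models,
        "n_chains": spec.n_chains,
        "pairs_per_model": n_dimers,
        "segment_start_resnum": start + 1,
        "segment_end_resnum": start + L,
        "segment_length": L,
        "prefix": prefix,
        "suffix": suffix,
        "prefix_count_per_model": chains_in_dimers if prefix else 0,
        "suffix_count_per_model": chains_in_dimers if suffix else 0,
        "prefix_count_total": (chains_in_dimers * spec.n_models
                               if prefix else 0),
        "suffix_count_total": (chains_in_dimers * spec.n_models
                               if suffix else 0),
        "method_class": classify_method(spec.method_text),
    }


DECOY_KINDS = ("helix", "hairpin", "far_pair", "curved_pair",
               "antiparallel_pair")

_GENERIC = "ARNDCQEGHILKMFPSTWYV"


def _generic_sequence(n: int) -> str:
    reps = -(-n // len(_GENERIC))
    return (_GENERIC * reps)[:n]


def generate_decoy(kind: str, seed: int = 0,
                   noise_sd: float = 0.0) -> StructureModel:
    """Negative-control structures, each violating exactly one constraint.

    helix
        A single-chain ideal alpha-helix (rise 1.5 A/residue, radius 2.3 A,
        100 degrees/residue): no second chain, and far below the
        straightness threshold.
    hairpin
        One chain that runs out, loops back and runs parallel to itself with
        arms 5 A apart: perfect strand-pair geometry, but on a single chain.
    far_pair
        Two parallel strands 20 A apart: violates only the 15 A ceiling.
    curved_pair
        Two concentric spiral chains 4.8 A apart: any window long enough to
        satisfy coverage is too curved for the straightness threshold.
    antiparallel_pair
        Two short strands 10 A apart with the second chain reversed:
        violates only the parallel-direction requirement.
    """
    if kind not in DECOY_KINDS:
        raise ValueError(f"unknown decoy kind {kind!r}; choose from {DECOY_KINDS}")
    rng = np.random.default_rng(seed)
    chains: list[ChainModel] = []
    if kind == "helix":
        n = 24
        i = np.arange(n)
        theta = np.radians(100.0) * i
        coords = np.stack([1.5 * i, 2.3 * np.cos(theta),
                           2.3 * np.sin(theta)], axis=1)
        coords = coords + _smooth_noise(rng, n, noise_sd)
        chains.append(_make_chain("A", _generic_sequence(n), coords))
    elif kind == "hairpin":
        arm, conn = 10, 8
        pts = [(3.4 * i, 0.0, 0.0) for i in range(arm)]
        x0, y0 = 3.4 * (arm - 1), 0.0
        for k in range(1, conn + 1):
            t = k / (conn + 1)
            pts.append((x0 * (1 - t), 5.0 * t, 0.0))
        pts.extend((3.4 * i, 5.0, 0.0) for i in range(arm))
        coords = np.array(pts) + _smooth_noise(rng, len(pts), noise_sd)
        chains.append(_make_chain("A", _generic_sequence(len(pts)), coords))
    elif kind == "far_pair":
        n = 12
        seq = _generic_sequence(n)
        a = np.stack([3.4 * np.arange(n), np.zeros(n), np.zeros(n)], axis=1)
        b = a + np.array([0.0, 20.0, 0.0])
        chains.append(_make_chain("A", seq, a + _smooth_noise(rng, n, noise_sd)))
        chains.append(_make_chain("B", seq, b + _smooth_noise(rng, n, noise_sd)))
    elif kind == "curved_pair":
        n, total_angle = 70, 14.0
        phi = total_angle * np.arange(n) / (n - 1)
        # inner radius chosen so consecutive chord length is ~3.4 A
        r_in = 3.4 * (n - 1) / total_angle
        seq = _generic_sequence(n)
        for cid, radius in (("A", r_in), ("B", r_in + 4.8)):
            coords = np.stack([radius * np.cos(phi), radius * np.sin(phi),
                               np.zeros(n)], axis=1)
            chains.append(_make_chain(
                cid, seq, coords + _smooth_noise(rng, n, noise_sd)))
    elif kind == "antiparallel_pair":
        n = 3
        seq = _generic_sequence(n)
        a = np.stack([3.4 * np.arange(n), np.zeros(n), np.zeros(n)], axis=1)
        b = np.stack([3.4 * np.arange(n - 1, -1, -1), np.full(n, 10.0),
                      np.zeros(n)], axis=1)
        chains.append(_make_chain("A", seq, a + _smooth_noise(rng, n, noise_sd)))
        chains.append(_make_chain("B", seq, b + _smooth_noise(rng, n, noise_sd)))
    entry = f"D{kind[:3].upper()}"
    return StructureModel(entry_id=entry, method_class=NMR,
                          models=[chains], raw_method="SOLUTION NMR")
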