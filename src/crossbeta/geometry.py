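"""Geometric detection of parallel beta-sheet segment pairs.

A parallel segment pair is two equal-length runs of C-alpha positions on
*distinct* chains whose per-position distances stay inside a fixed band
(default 2-15 A) with low spread (population standard deviation < 1.5 A),
whose segments are nearly straight (the curvature exclusion is
operationalized as end-to-end / contour length >= 0.9), that run the same
way (normalized end-to-end dot product >= 0.5, which rejects anti-parallel
sheets), and that cover at least one seventh of the resolved length of a
parent chain.  Requiring distinct chains excludes hairpins and beta-barrels;
the distance band with low variance is the in-register stacking signature of
cross-beta (amyloid) architecture.

Residue pairing is index-registered: residue i of the first segment pairs
with residue i + r of the second for a constant registration r; by default
only r = 0 is scanned (in-register stacking is the amyloid hallmark), and
``offset_scan`` widens the scan to |r| <= k.

Reported pairs are *maximal*: no reported window can be extended by one
residue at either end without violating a constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .structure_io import ChainModel, StructureModel

__all__ = [
    "GeometryParams",
    "ParallelSegmentPair",
    "WindowDiagnostics",
    "distance_profile",
    "straightness",
    "enumerate_parallel_pairs",
    "apply_coverage_filter",
    "evaluate_window",
    "chain_runs",
]


@dataclass(frozen=True)
class GeometryParams:
    """Thresholds of the parallel-sheet filter.

    d_min, d_max
        Pointwise inter-strand C-alpha distance band in Angstrom.
    sigma_max
        Upper bound (strict) on the population standard deviation of the
        distance profile, in Angstrom.
    coverage_min
        Minimum segment length as a fraction of the parent chain's resolved
        length; the filter passes when either chain satisfies it (both when
        ``coverage_both`` is set).
    min_segment_length
        Minimum residues per segment; three are needed so that a boundary
        prefix has a full three-residue core.
    straightness_min
        Minimum end-to-end / contour-length ratio of each segment.
    parallel_dot_min
        Minimum normalized dot product of the two segments' end-to-end
        vectors; positive values enforce parallel (not anti-parallel) runs.
    offset_scan
        Scan registrations |r| <= offset_scan; 0 keeps only in-register
        pairings.
    break_distance
        Consecutive C-alpha distance above which a chain is considered
        broken; no segment spans a break (nor an author-numbering gap > 1).
    """

    d_min: float = 2.0
    d_max: float = 15.0
    sigma_max: float = 1.5
    coverage_min: float = 1.0 / 7.0
    min_segment_length: int = 3
    straightness_min: float = 0.9
    parallel_dot_min: float = 0.5
    offset_scan: int = 0
    coverage_both: bool = False
    break_distance: float = 4.5

    def __post_init__(self) -> None:
        if not 0 < self.d_min < self.d_max:
            raise ValueError("need 0 < d_min < d_max")
        if self.sigma_max <= 0:
            raise ValueError("sigma_max must be positive")
        if not 0 < self.coverage_min <= 1:
            raise ValueError("coverage_min must be in (0, 1]")
        if self.min_segment_length < 3:
            raise ValueError("min_segment_length must be >= 3")
        if not 0 < self.straightness_min <= 1:
            raise ValueError("straightness_min must be in (0, 1]")
        if not 0 < self.parallel_dot_min <= 1:
            raise ValueError("parallel_dot_min must be in (0, 1]")
        if self.offset_scan < 0:
            raise ValueError("offset_scan must be >= 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_config(cls, path) -> "GeometryParams":
        """Read ``key = value`` lines into parameters; '#' starts a comment."""
        values: dict = {}
        valid = {f.name: f.type for f in fields(cls)}
        for raw in open(path):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in valid:
                raise ValueError(f"unknown geometry parameter {key!r}")
            value = value.strip()
            if key == "coverage_both":
                values[key] = value.lower() in ("1", "true", "yes", "on")
            elif key in ("min_segment_length", "offset_scan"):
                values[key] = int(value)
            else:
                # accept fractions like 1/7
                if "/" in value:
                    num, den = value.split("/")
                    values[key] = float(num) / float(den)
                else:
                    values[key] = float(value)
        return cls(**values)


@dataclass
class ParallelSegmentPair:
    """A detected maximal parallel segment pair and its filter diagnostics.

    ``start_a`` / ``start_b`` index into the residue lists of the parent
    chains; ``resnum_range_*`` give the inclusive author-numbering spans.
    """

    entry_id: str
    model_index: int
    chain_a: str
    start_a: int
    chain_b: str
    start_b: int
    length: int
    distances: np.ndarray
    mean_distance: float
    distance_sd: float
    straightness_a: float
    straightness_b: float
    coverage_a: float
    coverage_b: float
    direction_dot: float
    resnum_range_a: tuple[int, int]
    resnum_range_b: tuple[int, int]

    @property
    def registration(self) -> int:
        return self.start_b - self.start_a

    def key(self) -> tuple:
        return (self.chain_a, self.start_a, self.chain_b, self.start_b,
                self.length)


@dataclass
class WindowDiagnostics:
    """Per-constraint outcome for one candidate window (decoy forensics)."""

    separate_chains: bool
    contiguous: bool
    in_band: bool
    sd_ok: bool
    straight_a_ok: bool
    straight_b_ok: bool
    parallel_ok: bool
    coverage_ok: bool
    length_ok: bool
    failures: tuple[str, ...] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return not self.failures


def distance_profile(seg_a: np.ndarray, seg_b: np.ndarray) -> np.ndarray:
    """Per-position Euclidean distances between two index-registered runs."""
    a = np.asarray(seg_a, dtype=float)
    b = np.asarray(seg_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or len(a) < 1:
        raise ValueError("runs must be equal-length (L, 3) arrays with L >= 1")
    return np.linalg.norm(a - b, axis=1)


def straightness(seg: np.ndarray) -> float:
    """End-to-end distance over contour length of a C-alpha run.

    Equals 1 for collinear equally spaced points and decreases with
    curvature; a run of coincident points is treated as degenerate-straight.
    """
    coords = np.asarray(seg, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 2:
        raise ValueError("run must be an (n, 3) array with n >= 2")
    contour = float(np.linalg.norm(np.diff(coords, axis=0), axis=1).sum())
    if contour == 0.0:
        return 1.0
    return float(np.linalg.norm(coords[-1] - coords[0]) / contour)


def chain_runs(chain: ChainModel, break_distance: float = 4.5) -> list[tuple[int, int]]:
    """Break-free runs of a chain as inclusive (lo, hi) residue-index spans.

    A run contains only residues with a C-alpha; it ends at an
    author-numbering gap > 1 or a consecutive C-alpha distance above
    ``break_distance``.
    """
    runs: list[tuple[int, int]] = []
    residues = chain.residues
    lo = None
    for i, res in enumerate(residues):
        if not res.has_ca():
            if lo is not None:
                runs.append((lo, i - 1))
                lo = None
            continue
        if lo is None:
            lo = i
            continue
        prev = residues[i - 1]
        gap = res.author_seq_number - prev.author_seq_number
        dist = float(np.linalg.norm(res.ca_position - prev.ca_position))
        if not prev.has_ca() or gap > 1 or gap < 0 or dist > break_distance:
            runs.append((lo, i - 1))
            lo = i
    if lo is not None:
        runs.append((lo, len(residues) - 1))
    return runs


def apply_coverage_filter(pair: ParallelSegmentPair,
                          params: GeometryParams) -> bool:
    """Coverage rule: segment length over parent-chain resolved length.

    Passes when at least one chain reaches ``coverage_min`` (both chains
    when ``coverage_both`` is set); the bound is inclusive, so a length-2
    segment on a 14-residue chain sits exactly at the default 1/7.
    """
    if params.coverage_both:
        return (pair.coverage_a >= params.coverage_min
                and pair.coverage_b >= params.coverage_min)
    return max(pair.coverage_a, pair.coverage_b) >= params.coverage_min


class _ChainGeom:
    """Precomputed per-chain arrays used by the window scan."""

    def __init__(self, chain: ChainModel, break_distance: float):
        self.chain = chain
        n = chain.n_residues
        self.coords = np.full((n, 3), np.nan)
        for i, res in enumerate(chain.residues):
            if res.has_ca():
                self.coords[i] = res.ca_position
        self.run_id = np.full(n, -1, dtype=int)
        for rid, (lo, hi) in enumerate(chain_runs(chain, break_distance)):
            self.run_id[lo:hi + 1] = rid
        # cumulative contour length between consecutive residues (NaN-safe)
        step = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        self.contour = np.concatenate([[0.0], np.nancumsum(step)])
        self.resolved_length = chain.length

    def window_straightness(self, i: int, L: int) -> float:
        contour = self.contour[i + L - 1] - self.contour[i]
        if contour == 0.0:
            return 1.0
        e2e = float(np.linalg.norm(self.coords[i + L - 1] - self.coords[i]))
        return e2e / contour

    def direction(self, i: int, L: int) -> np.ndarray | None:
        v = self.coords[i + L - 1] - self.coords[i]
        norm = float(np.linalg.norm(v))
        if norm == 0.0:
            return None
        return v / norm


def _window_checks(ga: _ChainGeom, gb: _ChainGeom, i: int, j: int, L: int,
                   params: GeometryParams) -> dict:
    """Evaluate every constraint for window A[i:i+L] vs B[j:j+L]."""
    out = {}
    na, nb = len(ga.coords), len(gb.coords)
    inside = 0 <= i and i + L <= na and 0 <= j and j + L <= nb
    contiguous = bool(
        inside
        and ga.run_id[i] >= 0 and ga.run_id[i] == ga.run_id[i + L - 1]
        and gb.run_id[j] >= 0 and gb.run_id[j] == gb.run_id[j + L - 1]
    )
    out["contiguous"] = contiguous
    out["length_ok"] = L >= params.min_segment_length
    if not contiguous:
        out.update(in_band=False, sd_ok=False, straight_a_ok=False,
                   straight_b_ok=False, parallel_ok=False, coverage_ok=False,
                   distances=None)
        return out
    d = np.linalg.norm(ga.coords[i:i + L] - gb.coords[j:j + L], axis=1)
    out["distances"] = d
    out["in_band"] = bool(np.all((d >= params.d_min) & (d <= params.d_max)))
    sd = float(np.std(d))  # population form
    out["sd"] = sd
    out["sd_ok"] = sd < params.sigma_max
    sa = ga.window_straightness(i, L)
    sb = gb.window_straightness(j, L)
    out["straightness_a"], out["straightness_b"] = sa, sb
    out["straight_a_ok"] = sa >= params.straightness_min
    out["straight_b_ok"] = sb >= params.straightness_min
    da, db = ga.direction(i, L), gb.direction(j, L)
    dot = float(np.dot(da, db)) if da is not None and db is not None else 0.0
    out["direction_dot"] = dot
    out["parallel_ok"] = dot >= params.parallel_dot_min
    cov_a = L / ga.resolved_length if ga.resolved_length else 0.0
    cov_b = L / gb.resolved_length if gb.resolved_length else 0.0
    out["coverage_a"], out["coverage_b"] = cov_a, cov_b
    if params.coverage_both:
        out["coverage_ok"] = (cov_a >= params.coverage_min
                              and cov_b >= params.coverage_min)
    else:
        out["coverage_ok"] = max(cov_a, cov_b) >= params.coverage_min
    return out


_CHECK_KEYS = ("contiguous", "length_ok", "in_band", "sd_ok",
               "straight_a_ok", "straight_b_ok", "parallel_ok", "coverage_ok")


def _is_valid(checks: dict) -> bool:
    return all(checks[k] for k in _CHECK_KEYS)


def evaluate_window(structure: StructureModel, model_index: int,
                    chain_a: str, start_a: int, chain_b: str, start_b: int,
                    length: int, params: GeometryParams | None = None,
                    ) -> WindowDiagnostics:
    """Diagnose one candidate window against every constraint.

    Unlike :func:`enumerate_parallel_pairs` this accepts same-chain windows,
    so decoy structures can be asked *why* they fail (e.g. a hairpin's arms
    fail only the separate-chain rule).
    """
    params = params or GeometryParams()
    ca = structure.get_chain(model_index, chain_a)
    cb = structure.get_chain(model_index, chain_b)
    ga = _ChainGeom(ca, params.break_distance)
    gb = ga if cb is ca else _ChainGeom(cb, params.break_distance)
    checks = _window_checks(ga, gb, start_a, start_b, length, params)
    separate = chain_a != chain_b
    names = {
        "separate_chains": separate, "contiguous": checks["contiguous"],
        "length_ok": checks["length_ok"], "in_band": checks["in_band"],
        "sd_ok": checks["sd_ok"], "straight_a_ok": checks["straight_a_ok"],
        "straight_b_ok": checks["straight_b_ok"],
        "parallel_ok": checks["parallel_ok"],
        "coverage_ok": checks["coverage_ok"],
    }
    failures = tuple(k for k, ok in names.items() if not ok)
    return WindowDiagnostics(
        separate_chains=separate,
        contiguous=checks["contiguous"],
        in_band=checks["in_band"],
        sd_ok=checks["sd_ok"],
        straight_a_ok=checks["straight_a_ok"],
        straight_b_ok=checks["straight_b_ok"],
        parallel_ok=checks["parallel_ok"],
        coverage_ok=checks["coverage_ok"],
        length_ok=checks["length_ok"],
        failures=failures,
    )


def enumerate_parallel_pairs(
    structure: StructureModel,
    params: GeometryParams | None = None,
    model_index: int = 0,
) -> list[ParallelSegmentPair]:
    """All maximal parallel segment pairs of one model.

    Chains are taken in file order and each physical pair is reported once
    with ``chain_a`` preceding ``chain_b``.  A window is valid when every
    constraint of :class:`GeometryParams` holds; it is reported when neither
    one-residue extension (N- or C-terminal, keeping the registration) is
    itself valid.  Output is sorted by (chain_a, start_a, chain_b, start_b).
    """
    params = params or GeometryParams()
    chains = structure.models[model_index]
    geoms = [_ChainGeom(c, params.break_distance) for c in chains]
    results: list[ParallelSegmentPair] = []
    for ia in range(len(chains)):
        for ib in range(ia + 1, len(chains)):
            results.extend(_pairs_for_chain_pair(
                structure, model_index, chains[ia], geoms[ia],
                chains[ib], geoms[ib], params))
    results.sort(key=lambda p: (p.chain_a, p.start_a, p.chain_b, p.start_b))
    return results


def _pairs_for_chain_pair(structure, model_index, chain_a, ga, chain_b, gb,
                          params) -> list[ParallelSegmentPair]:
    na, nb = chain_a.n_residues, chain_b.n_residues
    out = []
    for r in range(-params.offset_scan, params.offset_scan + 1):
        valid: set[tuple[int, int]] = set()
        for i in range(max(0, -r), min(na, nb - r)):
            j = i + r
            if ga.run_id[i] < 0 or gb.run_id[j] < 0:
                continue
            max_len = min(na - i, nb - j)
            for L in range(params.min_segment_length, max_len + 1):
                checks = _window_checks(ga, gb, i, j, L, params)
                if not checks["contiguous"]:
                    break  # longer windows cross the same break
                if _is_valid(checks):
                    valid.add((i, L))
        for (i, L) in sorted(valid):
            if (i - 1, L + 1) in valid or (i, L + 1) in valid:
                continue
            j = i + r
            checks = _window_checks(ga, gb, i, j, L, params)
            d = checks["distances"]
            out.append(ParallelSegmentPair(
                entry_id=structure.entry_id,
                model_index=model_index,
                chain_a=chain_a.chain_id, start_a=i,
                chain_b=chain_b.chain_id, start_b=j,
                length=L,
                distances=d,
                mean_distance=float(np.mean(d)),
                distance_sd=checks["sd"],
                straightness_a=checks["straightness_a"],
                straightness_b=checks["straightness_b"],
                coverage_a=checks["coverage_a"],
                coverage_b=checks["coverage_b"],
                direction_dot=checks["direction_dot"],
                resnum_range_a=(
                    chain_a.residues[i].author_seq_number,
                    chain_a.residues[i + L - 1].author_seq_number),
                resnum_range_b=(
                    chain_b.residues[j].author_seq_number,
                    chain_b.residues[j + L - 1].author_seq_number),
            ))
    return out


def pairs_to_frame(pairs: list[ParallelSegmentPair]):
    """Detected pairs as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for p in pairs:
        rows.append({
            "entry": p.entry_id,
            "model": p.model_index,
            "chain_a": p.chain_a,
            "seg_a_range": f"{p.resnum_range_a[0]}-{p.resnum_range_a[1]}",
            "chain_b": p.chain_b,
            "seg_b_range": f"{p.resnum_range_b[0]}-{p.resnum_range_b[1]}",
            "length": p.length,
            "mean_distance": round(p.mean_distance, 3),
            "distance_sd": round(p.distance_sd, 3),
            "straightness_a": round(p.straightness_a, 4),
            "straightness_b": round(p.straightness_b, 4),
            "coverage_a": round(p.coverage_a, 4),
            "coverage_b": round(p.coverage_b, 4),
        })
    columns = ["entry", "model", "chain_a", "seg_a_range", "chain_b",
               "seg_b_range", "length", "mean_distance", "distance_sd",
               "straightness_a", "straightness_b", "coverage_a", "coverage_b"]
    return pd.DataFrame(rows, columns=columns)
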