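"""Shared test helpers: independent oracles and structure builders.

The brute-force pair enumerator and the naive substring scanner here are
deliberately written from the constraint definitions with plain loops,
independent of the library's implementation, so they can serve as oracles.
"""

from __future__ import annotations

import math
import random

import numpy as np

from crossbeta.geometry import GeometryParams
from crossbeta.structure_io import (
    NMR,
    ChainModel,
    ONE_TO_THREE,
    ResidueRecord,
    StructureModel,
)

AMINO = "ARNDCQEGHILKMFPSTWYV"

# Public sequences used for the synthetic stand-in structures (the named
# PDB entries themselves are not bundled): amyloid-beta 1-40 and the human
# p53 tetramerization-domain region.
ABETA40 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"
P53_TET = "KKPLDGEYFTLQIRGRERFEMFRELNEALELKDAQAGKE"


def make_chain(chain_id, letters, coords, numbers=None, missing_ca=()):
    """Build a ChainModel from one-letter codes and an (n, 3) array."""
    coords = np.asarray(coords, dtype=float)
    numbers = list(numbers) if numbers is not None else list(
        range(1, len(letters) + 1))
    residues = []
    for i, letter in enumerate(letters):
        residues.append(ResidueRecord(
            chain_id=chain_id,
            author_seq_number=numbers[i],
            insertion_code="",
            residue_name=ONE_TO_THREE.get(letter, "UNK"),
            one_letter=letter,
            ca_position=None if i in missing_ca else coords[i].copy(),
        ))
    return ChainModel(chain_id=chain_id, residues=residues)


def make_structure(chains, entry_id="TEST", method=NMR):
    return StructureModel(entry_id=entry_id, method_class=method,
                          models=[list(chains)])


def random_structure(rng: random.Random, max_chains=2, max_len=15):
    """Random small structure for oracle-equivalence testing.

    Mixes free random walks with correlated chain pairs (a copy of the
    first chain offset by roughly one strand spacing) so that positive
    detections actually occur, plus occasional numbering gaps and missing
    C-alphas to exercise the break rules.
    """
    n_chains = rng.randint(1, max_chains)
    chains = []
    first_coords = None
    for c in range(n_chains):
        n = rng.randint(3, max_len)
        correlated = (c > 0 and first_coords is not None
                      and rng.random() < 0.5)
        if correlated:
            n = len(first_coords)
            offset = np.array([rng.uniform(-1, 1),
                               rng.uniform(3.5, 6.0),
                               rng.uniform(-1, 1)])
            coords = first_coords + offset
            coords = coords + np.array(
                [[rng.gauss(0, 0.3) for _ in range(3)] for _ in range(n)])
        else:
            pos = np.array([rng.uniform(-5, 5) for _ in range(3)])
            pts = [pos]
            for _ in range(n - 1):
                step = np.array([rng.gauss(0, 1) for _ in range(3)])
                norm = np.linalg.norm(step) or 1.0
                length = rng.uniform(2.5, 5.0)
                pts.append(pts[-1] + step / norm * length)
            coords = np.array(pts)
            if c == 0:
                first_coords = coords
        numbers = list(range(1, n + 1))
        if rng.random() < 0.25:  # numbering gap somewhere
            cut = rng.randrange(1, n)
            numbers = numbers[:cut] + [x + rng.randint(2, 5)
                                       for x in numbers[cut:]]
        missing = set()
        if rng.random() < 0.2:
            missing.add(rng.randrange(n))
        letters = "".join(rng.choice(AMINO) for _ in range(n))
        chains.append(make_chain("ABCD"[c], letters, coords,
                                 numbers=numbers, missing_ca=missing))
    return make_structure(chains, entry_id="RND0")


def _window_valid(chain_a, chain_b, i, j, L, params: GeometryParams) -> bool:
    for chain, s in ((chain_a, i), (chain_b, j)):
        if s < 0 or s + L > chain.n_residues:
            return False
        res = chain.residues[s:s + L]
        if any(r.ca_position is None for r in res):
            return False
        for p, q in zip(res, res[1:]):
            gap = q.author_seq_number - p.author_seq_number
            if gap < 0 or gap > 1:
                return False
            if math.dist(p.ca_position, q.ca_position) > params.break_distance:
                return False
    dists = [math.dist(chain_a.residues[i + k].ca_position,
                       chain_b.residues[j + k].ca_position)
             for k in range(L)]
    if any(d < params.d_min or d > params.d_max for d in dists):
        return False
    mean = sum(dists) / L
    sd = math.sqrt(sum((d - mean) ** 2 for d in dists) / L)
    if not sd < params.sigma_max:
        return False
    for chain, s in ((chain_a, i), (chain_b, j)):
        pts = [chain.residues[s + k].ca_position for k in range(L)]
        contour = sum(math.dist(p, q) for p, q in zip(pts, pts[1:]))
        e2e = math.dist(pts[0], pts[-1])
        if contour > 0 and e2e / contour < params.straightness_min:
            return False
    va = np.asarray(chain_a.residues[i + L - 1].ca_position) - \
        np.asarray(chain_a.residues[i].ca_position)
    vb = np.asarray(chain_b.residues[j + L - 1].ca_position) - \
        np.asarray(chain_b.residues[j].ca_position)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return False
    if float(np.dot(va, vb) / (na * nb)) < params.parallel_dot_min:
        return False
    res_a = sum(1 for r in chain_a.residues if r.ca_position is not None)
    res_b = sum(1 for r in chain_b.residues if r.ca_position is not None)
    cov_a = L / res_a if res_a else 0.0
    cov_b = L / res_b if res_b else 0.0
    if params.coverage_both:
        return cov_a >= params.coverage_min and cov_b >= params.coverage_min
    return max(cov_a, cov_b) >= params.coverage_min


def brute_force_pairs(structure, params=None, model_index=0):
    """Exhaustive enumeration of maximal valid windows (the oracle).

    Returns sorted (chain_a, start_a, chain_b, start_b, length) tuples.
    """
    params = params or GeometryParams()
    chains = structure.models[model_index]
    found = []
    for ia in range(len(chains)):
        for ib in range(ia + 1, len(chains)):
            A, B = chains[ia], chains[ib]
            for r in range(-params.offset_scan, params.offset_scan + 1):
                valid = set()
                for i in range(A.n_residues):
                    for L in range(params.min_segment_length,
                                   A.n_residues - i + 1):
                        if _window_valid(A, B, i, i + r, L, params):
                            valid.add((i, L))
                for (i, L) in valid:
                    if (i - 1, L + 1) in valid or (i, L + 1) in valid:
                        continue
                    found.append((A.chain_id, i, B.chain_id, i + r, L))
    return sorted(found)


def pair_keys(pairs):
    return sorted((p.chain_a, p.start_a, p.chain_b, p.start_b, p.length)
                  for p in pairs)


def naive_scan(kmer, sequence):
    """Character-by-character overlapping substring scan (oracle)."""
    kmer = kmer.upper()
    sequence = sequence.upper()
    hits = []
    for start in range(len(sequence) - len(kmer) + 1):
        window = sequence[start:start + len(kmer)]
        if "X" in window:
            continue
        if all(window[k] == kmer[k] for k in range(len(kmer))):
            hits.append(start + 1)
    return hits


def merge_structures(entry_id, *structures, method="SOLID-STATE NMR",
                     y_spacing=60.0):
    """Compose several generated sheets into one multi-segment entry.

    Chains are renamed serially and each component is displaced along y so
    the components stay outside each other's detection band.  All
    components must have the same model count.
    """
    from crossbeta.structure_io import classify_method

    n_models = structures[0].n_models
    assert all(s.n_models == n_models for s in structures)
    models = []
    for mi in range(n_models):
        chains = []
        letters = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        for si, st in enumerate(structures):
            for chain in st.models[mi]:
                cid = next(letters)
                residues = []
                for r in chain.residues:
                    pos = None if r.ca_position is None else \
                        r.ca_position + np.array([0.0, si * y_spacing, 0.0])
                    residues.append(ResidueRecord(
                        chain_id=cid,
                        author_seq_number=r.author_seq_number,
                        insertion_code=r.insertion_code,
                        residue_name=r.residue_name,
                        one_letter=r.one_letter,
                        ca_position=pos,
                    ))
                chains.append(ChainModel(chain_id=cid, residues=residues))
        models.append(chains)
    return StructureModel(entry_id=entry_id,
                          method_class=classify_method(method),
                          models=models, raw_method=method)
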