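# Methods

## Detection model

A candidate is a pair of equal-length Cα windows on two distinct chains of
one model, paired index-to-index at a constant registration r (residue i of
window A against residue i + r of window B). By default only r = 0 is
scanned: in-register stacking is the defining feature of the cross-β
amyloid architecture, and scanning all registrations would additionally
report every off-register sub-alignment of an ideal fibril as its own
maximal pair. `GeometryParams.offset_scan = k` widens the scan to |r| ≤ k
for structures where strands are staggered.

A window is **valid** when all of the following hold:

| parameter | default | meaning |
|---|---|---|
| `d_min`, `d_max` | 2.0, 15.0 Å | pointwise band on every per-position Cα–Cα distance |
| `sigma_max` | 1.5 Å | strict upper bound on the distance-profile standard deviation |
| `straightness_min` | 0.9 | end-to-end / contour length of each window |
| `parallel_dot_min` | 0.5 | normalized dot product of the two end-to-end vectors |
| `coverage_min` | 1/7 | window length over parent-chain resolved length, inclusive |
| `min_segment_length` | 3 | needed so a boundary prefix has a 3-residue core |
| `break_distance` | 4.5 Å | consecutive Cα–Cα distance that severs a chain |

A valid window is **reported** when neither one-residue extension
(N-terminal or C-terminal, registration kept) is itself valid. Overlapping
maximal windows can coexist; each physical chain pair is reported once,
with `chain_a` preceding `chain_b` in file order.

Numerical choices:

- The distance band applies *pointwise* (every `d_k` inside [2, 15] Å),
  not to the mean; this is the stricter and more literal reading.
- The standard deviation uses the population form (denominator L). For the
  profile lengths involved the difference to the sample form is well below
  the 1.5 Å threshold's discriminating margin.
- Straightness of a run of coincident points is defined as 1.0
  (degenerate, never reached by real chains).
- The curvature exclusion has no published numeric threshold; the
  end-to-end/contour ratio ≥ 0.9 is this package's operationalization,
  calibrated against decoys: an ideal α-helix trace (rise 1.5 Å/residue,
  radius 2.3 Å, 100°/residue) scores ≈ 0.39, a semicircular arc 2/π ≈
  0.637, a gently curved long sheet < 0.9, while β-strands with realistic
  coordinate noise stay well above 0.9. Detected entry sets may be
  sensitive to this choice near the boundary; the value is exposed in
  `GeometryParams` and in every manifest.
- Parallel vs anti-parallel is decided by the sign and size of the
  end-to-end dot product; 0.5 (60°) tolerates fibril twist while cleanly
  rejecting reversed strands (dot ≈ −1).
- Coverage passes when *either* chain reaches 1/7 (the `--coverage-both`
  flag demands both); the denominator is the count of residues with a
  resolved Cα, not the SEQRES length, because unresolved residues carry no
  geometric evidence.
- Monotonicity of the filter under parameter relaxation holds in the
  containment sense: every pair reported under a narrower band/sd cap is
  contained in a pair reported under the wider one (relaxation can merge a
  maximal window into a longer maximal window, so identity of the reported
  tuples is not preserved — containment is the meaningful invariant).

## Boundary 5-mers

The prefix of a detected segment is the 5-mer XXYYY: the two residues
immediately preceding the segment in N→C order (XX) plus the segment's
first three residues (YYY); the suffix mirrors this at the C-terminal end
(last three + two following). Both chains of a pair contribute. A 5-mer is
discarded when fewer than two flanking residues exist, when the five
residues are not sequence-contiguous, or when any letter is 'X'
(non-standard residue; MSE is mapped to M by default).

Flank contiguity is an author-numbering notion (gap ≤ 1, insertion codes
allowed). The geometric break heuristic (4.5 Å) gates *segment
membership* only: the boundary prefix is a sequence construct, and
coordinate noise in a coil flank must not sever a sequence-adjacent
boundary.

Counting is raw multiplicity — deliberately without homology or redundancy
correction — partitioned by experimental method class (NMR, including
solid-state; XRAY; OTHER). One count is registered per distinct boundary
site: (entry, model, chain, boundary residue, side). A site shared by
several overlapping reported pairs counts once; the same site recurring in
every model of an NMR ensemble counts once per model. Because deposited
entries do not decompose their multiplicities over models, both conventions
are first-class: the default counts every model, `--first-model-only`
restricts to the first, and the Table-1 comparison reports both. Rankings
break count ties lexicographically.

## Synthetic data: what it emulates, what it does not

`generate_parallel_sheet` builds in-register parallel fibrils with known
ground truth: n chains carrying a user-chosen sequence, strand residues
laid out as straight extended runs at `rise_per_residue` (default 3.4 Å)
spacing along the strand axis, facing their partner at
`inter_strand_spacing` (default 4.8 Å, the canonical cross-β stacking
distance), with optional progressive twist.

Design elements that make the ground truth exact:

- **Dimeric protofilaments.** Chains are grouped in pairs; successive
  pairs sit 25 Å apart, outside the detection band — mirroring real fibril
  architectures in which the protofilament interface is not an in-register
  parallel contact. Within one sheet of > 2 chains, no symmetric placement
  of boundary residues can terminate window growth for every adjacent pair
  simultaneously, so the dimer is the unit that guarantees planted
  boundaries are recovered exactly for any chain count.
- **Converging boundary coil.** All non-strand residues of the two chains
  of a dimer converge to ~0.3 Å apart (and sit ≥ 1 Å off the strand axis
  with a small zig-zag). Extending a detected window by one residue
  therefore adds a pair below the 2 Å floor, making the planted window the
  unique maximal detection and the extracted prefix exactly the planted
  XX+YYY letters.
- **Smooth noise.** `noise_sd` adds a correlated Gaussian displacement
  field (per-coordinate sd = `noise_sd`, correlation length ~3 residues).
  Independent per-atom noise of 0.3 Å would stretch consecutive Cα
  pseudo-bonds past the 4.5 Å break threshold in a sizeable fraction of
  chains, tearing segments that real thermal/ensemble variation — which is
  spatially correlated — leaves intact.

Five decoy families each violate exactly one constraint: `helix`
(single-chain, and far below the straightness bar), `hairpin` (a chain
meandering back parallel to itself at 5 Å — perfect pair geometry on *one*
chain), `far_pair` (strands at 20 Å), `curved_pair` (concentric 70-residue
spirals: every window long enough for 1/7 coverage is too curved),
`antiparallel_pair` (short strands at 10 Å, second chain reversed, so only
the direction test fails).

What the generator does **not** emulate: full-backbone/side-chain
geometry, β-sheet pleating and hydrogen-bonding detail, heterogeneous
sequences across chains, crystallographic packing, disorder, or
experimental coordinate error structure. Passing the synthetic suite
therefore demonstrates the correctness of the geometry, extraction,
counting and search machinery under controlled conditions — not the
field-accuracy of the thresholds on deposited structures, which requires
the real entries as inputs.

## Pipeline and reproduction recipe

`run_pipeline` isolates failures per input file (statuses `ok`,
`parse-error`, `empty` in the manifest), processes every model (or the
first only), and writes `counts.tsv` / `manifest.json` atomically. Outputs
are deterministic for fixed inputs and parameters; the manifest timestamp
is opt-in so that reruns are byte-identical.

`reproduce_table1` lines up computed counts for the five headline prefixes
(QKLVF, GEYFT, HHQKL, HQKLV, GGERA, published counts 77/48/36/25/106)
against their published entry lists, under both model-counting modes, with
a per-entry breakdown so any residual discrepancy is attributable to a
documented choice (curvature threshold, model counting). One published
entry list exists in two variants (2Y42 vs 4Y42); either is accepted. The
deposited structure files are user-supplied inputs; missing entries are
listed and a partial report is produced. The bundled test corpus rebuilds
each named entry as a synthetic stand-in planting the attributed prefixes
(from the public amyloid-β and p53 tetramerization-domain sequences and a
constructed cyanase-like motif carrier), which validates entry-list
matching and counting mechanics; count equality with the published values
is only meaningful with the deposited files.

## Problem sizes used in the checks

The acceptance script and test suite run entirely on synthetic data:
200 random small structures (≤ 2 chains × ≤ 15 residues) for brute-force
equivalence, 50 seeded fibrils at 0.3 Å noise for planted recovery,
5 decoy families × 10 seeds, 1000 random sequences for search
equivalence, and a 10-file corpus for the end-to-end pipeline run. These
sizes give exhaustive oracles and stable statistics while keeping a full
run in seconds.

## Known limitations

- Secondary structure is inferred from Cα geometry only; no DSSP/STRIDE
  hydrogen-bond assignment, and no β-barrel topology analysis.
- In-register (r = 0) pairing is the default; staggered sheets need
  `offset_scan` > 0, which can also surface off-register sub-alignments.
- Whole-database searches operate on user-supplied FASTA; the package does
  not download or mirror any repository.
- ATOM-derived sequences are the default search substrate; SEQRES
  sequences are used only when present in PDB-format input and requested.
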