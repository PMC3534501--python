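# Methods

## Model and assumptions

`domaincut` treats a structural domain as a compact region with a higher
density of internal contacts than of contacts to the rest of the
structure. Both pipelines reduce a structure to point or vector objects,
build a pairwise distance matrix in Ångströms, agglomerate it, and decide
where (and whether) to cut the merge tree. No chain-continuity assumption
is made anywhere before the final clean-up, which is why multi-chain
complexes and genetic domains need no special handling: the Cα sets or
element sets of all selected chains are clustered jointly.

### Agglomeration

Average linkage is the default and the operating choice for both
algorithms; complete linkage is available for the SS pipeline. The
implementation maintains the distance matrix under the Lance–Williams
update (`d(A∪B,C) = (|A|d(A,C)+|B|d(B,C))/(|A|+|B|)` for average linkage,
max for complete) and at every step merges the globally closest pair.
Exact ties are broken toward the lexicographically smallest pair of
cluster ids (leaves 0..N−1, then merge nodes in creation order), which
makes every downstream result deterministic bit-for-bit. Average and
complete linkage are both reducible, so merge heights are non-decreasing
and the tree cut below is well defined.

### The gap cut (m, s)

The cut descends the distance axis from the root height `D`:

1. if `D < m`, stop — the structure is a single domain;
2. if no merge node has height in `[D − s, D)`, cut at `D − s/2`;
3. otherwise set `D` to the largest merge height in that window and
   repeat.

The half-open window means a node exactly at `D` counts as already
traversed and a node exactly at `D − s` keeps the descent going; this
guarantees strict progress and termination in at most N−1 steps. Because
step 2 fires only when the open interval `(D − s, D)` is merge-free, any
cut level inside the gap yields the same partition; `D − s/2` is purely
presentational (it is reported as `cut_height`). A single global cut is
made — the procedure is not applied recursively per cluster. Defaults
m = 22 Å, s = 5 Å are the tuned operating point for both pipelines;
raising either parameter monotonically biases the result toward fewer
domains (a property the tests assert).

### CA pipeline specifics

Burial: a residue is buried iff at least 9 *other* Cα lie within 7 Å
(the residue itself is not counted; neighbour search uses a k-d tree and
is verified against an all-pairs count in tests). Only buried residues
are clustered; with fewer than two buried residues — small peptides,
extended coils — the pipeline returns one domain with a warning rather
than failing. Exposed residues are attached to the cluster of their
nearest buried Cα *before* clean-up, ties toward the lower residue
index.

The optional intra-element constraint pins buried pairs inside one
helix/strand to 4 Å (≈ the bonded Cα–Cα distance), discouraging
mid-element boundaries; it is on by default. The analogous same-sheet
constraint (DSSP sheet letters) is off by default: it helps some β-rich
structures but is not generally advantageous, so it is left to the user.

Clean-up: (1) domains with fewer residues than 10% of the largest
domain's count (strict `<`) are deleted, and each orphaned residue joins
the domain of its spatially nearest retained residue — deletion alone
would violate completeness, so reassignment is the package's resolution
of that gap; (2) per chain, a left-to-right scan absorbs any maximal
same-domain segment under 20 residues that is enclosed by one same other
domain on both sides or touches a chain end. The scan repeats until a
pass makes no change, which handles cascades (each absorption removes at
least one domain boundary, so it terminates). A short segment flanked by
two *different* domains is deliberately left untouched. Domains are
renumbered 1..k in order of first appearance along the sequence.

### SS pipeline specifics

DSSP codes H, G and I all map to helix (3₁₀ and π helices are
geometrically helical); E maps to strand; everything else is coil.
Element runs split at chain boundaries and at chain breaks — a
consecutive Cα–Cα distance above 4.5 Å or a jump in author numbering.
Runs shorter than 3 residues are demoted to coil: a principal axis needs
at least three points to be meaningful, and two-residue "strands" are
noise. The same element definition feeds the CA pipeline's intra-element
constraint, for consistency.

An element's direction is the eigenvector of the 3×3 coordinate
covariance with the largest eigenvalue, sign-fixed so it points N→C;
endpoints are the projections of the first/last Cα onto the axis line
through the centroid. When the top two eigenvalues tie (numerically
degenerate, e.g. symmetric point sets) the axis with the largest |x|,
then |y|, component is chosen and a warning logged. Helices and strands
curve, but gently enough that one vector per element suffices.

Element distances use segment midpoints by default (the better-performing
metric; closest approach of the two segments is the alternative).
Sequence-adjacent same-chain elements may be pinned to 4 Å, which keeps
consecutive elements together unless the geometry clearly separates them
and reduces fragmented assignments; this adjacency constraint is on by
default. After cutting, clusters of ≤ 2 elements are dissolved and their
elements reassigned to the retained cluster with the smallest average
distance (dropping them would orphan residues); if no cluster has ≥ 3
elements everything collapses to one domain. Fewer than 3 elements in
total is an error directing the user to the CA algorithm — the package's
concrete definition of "insufficient secondary structure", configurable
via `SSParams.min_elements_required`. Residue boundaries fall after
residue `floor((last_of_prev + first_of_next)/2)` (internal indexing)
between consecutive elements of different clusters; residues outside the
first/last element join the terminal element's domain, and residues of a
chain with no element at all join the cluster of the spatially nearest
element midpoint.

## Evaluation

A prediction is compared to a reference only on their shared residues. If
the domain counts differ the assignment is incorrect outright; otherwise
the overlap is the matched-residue fraction under the best bijection
between label sets — exhaustive over k! permutations for k ≤ 8, Hungarian
assignment on the k×k contingency table above that (the two are verified
equal in tests for k ≤ 6). Correct means counts match and overlap ≥ 0.75
(0.90 for strict benchmarking). The per-class MCC treats "does this chain
have exactly k domains" as a binary classification over a record set and
applies the standard formula, with a zero denominator mapped to 0; this
binary-per-count construction is the package's documented
interpretation. The random baseline draws a domain count from a supplied
domains-per-chain distribution and splits the chain into equal contiguous
blocks; the shipped default marginal (0.75, 0.17, 0.06, 0.02) anchors
the single-domain mass at 75%, the value characteristic of non-redundant
chain sets, with the multi-domain tail spread by the package — supply a
measured distribution for serious baselining.

## Synthetic structures

`make_globule_structure` emulates exactly the property the algorithms
exploit: compact regions with high internal contact density. Each domain
is a 3.8 Å-step self-avoiding random walk (minimum non-bonded distance
3.0 Å, keeping burial counts realistic) confined to a sphere; domain
centres sit on a line at a controllable separation. Defaults — two
domains, 60 residues each, 10 Å packing radius, 40 Å separation — give
unambiguously separated compact bodies. Walk generation uses bounded
rejection (300 tries per step, 60 restarts) and raises a generation error
on infeasible packing. What the generator does *not* emulate: real
backbone dihedral geometry, side chains, hydrogen-bonded secondary
structure, or the soft, interpenetrating interfaces of real two-domain
proteins. Perfect recovery on these fixtures therefore demonstrates the
pipeline's mechanics (burial, clustering, cut, clean-up, bookkeeping),
not benchmark-level accuracy on the PDB, where domain interfaces are far
less crisp. SS-pipeline tests use ideal helices (1.5 Å rise, 100°/residue,
2.3 Å radius) with labels supplied directly, since random walks have no
DSSP-assignable secondary structure.

## Numerical choices and problem sizes

Distance matrices are validated for symmetry (1e-9) and a zero diagonal.
The clustering is O(N²) memory and ~O(N³) worst-case time, comfortably
fast for the ≤ ~1000 buried residues of typical inputs. Acceptance-style
checks run on deliberately small problems — 50 generator seeds per
recovery experiment, 100 random matrices of N ≤ 12 for the oracle
comparison, 120-residue structures — chosen so the whole suite completes
in seconds while still exercising every branch. The independent oracles
are a naive reference agglomerator that recomputes averages from the raw
matrix, scipy's linkage on tie-free matrices, a 1000×1000 dense-sampling
oracle for segment distance, and closed-form constructions for helix
geometry.

## Handling of structure files

Only the first model of multi-model (NMR) files is used; alternate
locations other than blank/'A' are dropped; waters and non-peptidic
heteroatoms are removed while non-standard amino acids with a Cα (MSE
etc.) are kept. Calcium ions named "CA" are excluded by element. Author
numbering with insertion codes is the public coordinate system for all
outputs; reference range files ignore insertion codes on endpoints.

## Known limitations

- Parameters are tuned for domains of typical size; structures with very
  small domains tend to come out under-cut, and coordinates of chains
  near the cut threshold can flip the result between replicate chains.
- The CA pipeline is sensitive to which chains are supplied: a chain that
  donates part of a genetic domain changes the partition of its partner,
  so assignments are best run on the biological unit.
- No consensus mode over multiple copies of a chain.
- DSSP is consumed as a file (classic, mmCIF-style, or a 3-column TSV),
  never invoked; the package assigns no secondary structure itself.
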