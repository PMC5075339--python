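# Methods

This note documents the models implemented in `cmiphmm`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## The interaction-profile HMM

The ipHMM is a profile HMM over a domain family's match columns in which
every match position *j* carries two emitting match states, non-interacting
`M_ni(j)` and interacting `M_i(j)`, alongside the usual insert states
`I(0..L)` and silent delete states `D(1..L)`.  Connectivity follows the
classic profile architecture: Begin feeds `{M*(1), D(1), I(0)}`; match
states feed `{M*(j+1), I(j), D(j+1), End}`; inserts self-loop and feed the
next column; deletes chain forward.  Both match flavors of a column share
the same alignment coordinate, so decoding a sequence assigns each aligned
residue a posterior split between "interacting" and "non-interacting" at
its column.

**Estimation.**  Maximum likelihood from a labeled alignment: `M_i(j)`
emissions from residues labeled interacting in column *j*, `M_ni(j)` from
the non-interacting ones, inserts from insert-column residues, and
transitions from each row's implied state path (match flavor from the
label, deletes from gaps).  Every emission cell and every allowed arc
receives an additive pseudocount (default 1, "add-one"), so all
probabilities are strictly positive and unseen amino acids keep nonzero
emission probability.  The pseudocount trades variance for a bias of
`20k/(n + 20k)` toward uniform on each emission vector; estimation-accuracy
studies in the test suite therefore use a small pseudocount (0.1), the
near-ML regime.

**Decoding.**  Forward-backward in log space with explicit in-level
topological propagation through the silent states (the delete chain and
End), using log-sum-exp throughout.  The forward and backward totals are
asserted to agree within 1e-8 relative on every call.  Posteriors γ(i, s)
normalize to one over emitting states per residue.  Per match column,

    p_int(j) = Σ_i γ(i, M_i(j)) / Σ_i [γ(i, M_i(j)) + γ(i, M_ni(j))],

and the site call is interacting iff `p_int > 0.5`; an exact tie goes to
the majority class (non-interacting).  Columns with no posterior-assigned
residue are deleted: call non-interacting, `p_int = 0`.  The
residue-to-column assignment used for feature extraction is the argmax of
per-residue match posterior mass — consistent with posterior decoding
rather than a Viterbi path.

**Fisher scores.**  For residue *i* aligned (by posterior argmax) to
column *j**, the score vector is the constrained gradient of the
log-likelihood with respect to that column's emission parameters,
restricted to the residue's term:

    F_i(a) = Σ_{m ∈ {M_ni, M_i}} γ(i, m(j*)) · (1[x_i = a] − e_{m(j*)}(a)).

Because Σ_a 1[x_i = a] = Σ_a e(a) = 1, every Fisher vector sums to zero;
this identity is asserted at 1e-6 across the suite.  Residues with zero
posterior match mass (pure inserts) get a zero vector and are flagged.

## Contact-matrix prediction

A residue pair (one residue per domain) is represented by
`[Fisher_A (20), window_A (187), Fisher_B (20), window_B (187)]` — 414
features.  The window block covers 11 sequence positions centered on the
residue (five on each side), each contributing the 17 amino-acid property
values of the packaged AAindex-style table, offset-major.  Window slots
beyond the sequence ends are filled with per-property means over the
training sequences (neutral after min-max scaling; zero-padding is
available via configuration).  "Spatially neighboring" is read as sequence
neighbors: no structure exists at prediction time.

Features are min-max scaled to [0, 1] per feature on the training fold;
constant features map to 0 and test values are clamped.  An RBF-kernel SVM
(`C = 1`) classifies each match-column pair; the binary matrix is the sign
of the decision value and the score matrix keeps the value itself.  Cells
whose row or column the sequence deletes are 0 / minimum score.

Two defaults depart from the simplest reading and are worth recording:

* **Kernel width.**  The kernel width is the SVM library's default
  `gamma = "scale"` = 1/(n_features · Var(X)).  The older convention
  1/n_features is nearly flat on 414-dim min-max-scaled vectors (typical
  squared distances of 40-60 give kernel values within a few percent of
  each other), and under the strong contact/non-contact imbalance the
  C = 1 optimum then degenerates to the constant classifier.
* **Class balance.**  Desk-scale families provide only tens of positive
  cells against ~1500 negatives per training fold, where a soft-margin SVM
  will happily ignore the minority class; contacts are therefore randomly
  oversampled to parity by default (seeded, training folds only).  The
  flag exists because with matrices at the 150-residue scale the cell
  counts are two orders of magnitude larger and no resampling is needed.

## The integrated site classifier

Domain-A residues take their row of the (binary) predicted contact matrix,
domain-B residues their column, with the residue's own `p_int` appended as
the last feature — length partner-L + 1.  Variants: `cm_only` drops the
last slot; `ground_truth_cm` substitutes the true matrix.  One
L2-penalized logistic regression (`C = 1`, lbfgs, tol 1e-6, max 1000
iterations; non-convergence is flagged, not fatal) is trained per family,
domain and variant on the training pairs' residues, positives oversampled
with replacement to parity and shuffled under a per-fold seed.  The
continuous posterior (not the binary call) is the default last-slot
feature — it is the richer signal; a flag switches to the binary call.

## Cross-validation protocol

Family-wise leave-one-out in two passes.  Pass 1, per held-out pair: both
domain ipHMMs are rebuilt from alignments with that pair's rows removed,
all sequences are decoded, the contact SVM is trained on the remaining
pairs' residue pairs (labels from their ground-truth matrices, alignment
coordinates), and the held-out pair's contact matrix and site posteriors
are predicted (posterior coordinates) and *reserved*.  Pass 2, per
held-out pair: the site models are trained on the remaining pairs'
reserved features — each training pair's contact features come from its
own out-of-fold predicted matrix — and tested on the held-out pair's
reserved features.  Using reserved matrices on both sides keeps the
feature distribution identical between training and testing; training on
in-sample matrices instead makes the contact features look optimistically
clean during training and measurably degrades the integrated model.  The
held-out pair's labels never enter any training stage; residues are
evaluated on the non-deleted match columns of their alignment row.

Tenfold cross-validation over pairs is available behind a flag (requiring
≥ 10 pairs); leave-one-out is the default protocol.  Macro-averaging is
per sequence across all families; metrics with zero denominators are
carried as null markers and excluded from means with an exclusion count.
The paired t-test is classical two-sided on per-sequence MCC differences,
df = n − 1; zero-variance nonzero differences are reported as degenerate
(infinite t) rather than raising.

## The synthetic family generator

The generator exists so every stage is trainable and testable with no
external data; it is matched to the method's assumptions deliberately, so
that benchmark results read as correctness checks of the pipeline, not as
biological claims.

Per family: each match column has a conserved consensus residue carrying
`1 − substitution_rate` of the emission mass (default 0.96), the rest on
three alternates.  A fraction `frac_interface` (default 0.25) of columns
per domain are interface columns, split into **core** columns (default
half), engaged in every family member, and **rim** columns, independently
active per pair with probability `1 − inactivation_rate` (default 0.65) —
the core/rim distinction mirrors the hot-spot/periphery organization of
real interfaces.  Engaged interface columns emit from a distinct (and for
`emission_sharpness > 1` more conserved) consensus; as
`emission_sharpness → 0` the engaged distribution blends into background,
removing the sequence signal entirely (the default, 2, is the fully
distinct regime).  A family-level bipartite contact pattern connects
interface columns assortatively (core-core and rim-rim) with edge density
`contact_density` (default 0.2, i.e. typical degree one), every interface
column participating.  A pair's contact matrix realizes exactly the
pattern edges whose two endpoint columns are active in that pair, and a
residue is labeled interacting iff its column has at least one contact in
its own pair's matrix — the label a structure-derived dataset would
assign, which also guarantees the consistency the ground-truth-CM variant
relies on (interacting ⇔ nonzero row).  Indels are applied per column at
`indel_rate` (default 0.03); optional `label_noise` flips emitted labels.

This architecture creates two distinct information channels, and the
method comparison hinges on them.  A rim residue that is active while all
its pattern partners are inactive is *not* interacting, but nothing in its
own sequence says so: the own-domain ipHMM systematically over-calls these
residues, while the contact matrix carries the partner information — this
is why the integrated model beats the plain ipHMM.  Conversely, when the
SVM misses a core contact (a false-negative row), the residue's `p_int`
still rescues the call — this is why the integrated model beats CM-only.
The defaults were chosen to make both channels active at desk scale.

What the generator does **not** emulate: real amino-acid composition or
property correlations, phylogenetic relatedness between members (rows are
i.i.d. given the family parameters), structural contact geometry, multiple
interface topologies per family, and realistic conservation levels
(columns are far more conserved than typical Pfam columns, which is what
makes parameter-recovery checks sharp at 200 members).  Passing benchmarks
therefore demonstrate that the implementation is correct and that the
integration mechanism works when its assumptions hold — not that it will
match any particular performance level on real DDI data.

## Problem sizes and runtime

The default benchmark is 10 families of 10-14 pairs with 12 + 14 match
columns (jittered), chosen so a full four-method leave-one-out sweep of
the suite completes in a few minutes on one CPU; the parameter-recovery
study uses a single 200-member noiseless family.  All stochastic steps
(family generation, oversampling, fold assignment) derive from explicit
integer seeds; repeated runs are bitwise identical.

## Known limitations

* The AAindex table shipped with the package carries synthetic stand-in
  values under the real 17 accession names (the property database itself
  is not redistributable here); any AAindex1-format file can be
  substituted.  Min-max normalization makes the pipeline insensitive to
  per-property affine changes, but absolute property values in the
  packaged table are not literature values.
* Contact matrices are defined in match-state coordinates; insert-state
  residues have no row/column and cannot be predicted as contacts.
* Per-family models only: nothing is shared across families, matching the
  family-wise protocol, so the package does not address cross-family
  generalization.
* The SVM stage exposes `gamma` and `C` but performs no hyperparameter
  search.
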