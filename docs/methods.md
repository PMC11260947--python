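# Methods

This note documents the model behind the package: what the procedures
assume, the choices made where the design was genuinely open, what the
synthetic generators do and do not emulate, and the numerical conventions.

## The filename grammar and tree

The grammar is four underscore-separated tokens plus an extension:
patient `H` + a zero-padded integer of at least three digits (`H\d{3,}` —
the width can grow past 999 patients), acquisition `CT`/`MR` + at least
three digits (numbering reflects acquisition order; assigning it happens
upstream and is not validated here), then free alphanumeric phase and tag
tokens. Phase and tag tokens are case-sensitive: `Porto` and `porto` are
distinct phases, because silently case-folding identifiers invites
collisions in a dataset where names *are* the schema.

Extensions are split off before tokenizing, with a compound-extension
list (`nii.gz`, `tar.gz`) checked first so that the dominant volume format
is not corrupted by naive last-dot splitting. A name with any other token
count, an empty token, or a malformed patient/acquisition token is
rejected outright. Parsing and formatting are exact inverses on their
respective domains; the parse∘format round trip is property-tested over
generated keys.

Placement uses only the first three tokens: an image and all of its label
files share one level-four directory. Per-patient clinical records are the
one deliberate exception to the grammar: a JSON named `<patient>.json`
(e.g. `H001.json`) is a clinical record and goes to level two.

## Structuring

The tree builder scans the drop-off directory recursively but ignores any
directory structure it finds — only bare filenames matter, so a staging
area produced by the re-integration step (or a nested export) structures
identically to a flat one. Files are *moved*, not copied: the drop-off is
an inbox, and an emptied inbox makes the operation idempotent (a second
run reports nothing to do).

Malformed names are quarantined in place with a reason and the batch
continues; a curation run must complete and report rather than die on file
7,312 of 10,000. Destination collisions default to an error — silently
overwriting patient data is never acceptable — with explicit `skip` and
`overwrite` policies available. Every move and quarantine is appended to a
plain-text audit log (`mds_audit.log`) in the dataset root.

Clinical CSV cells are kept as text unless they coerce cleanly to an
integer or float; empty cells become JSON `null`. Column order is
preserved, and the CSV → per-patient JSON → reassembled-table round trip
is exact under this convention. Two rows for one patient are an error, not
a merge.

## Pseudonymization

The extraction step draws pseudonyms exactly as a clerk with a shuffled
number list would: build 1..N for the N distinct patients in the request,
shuffle once with a seeded generator (`numpy.random.default_rng(seed)`),
and consume the shuffled sequence front-first in patient order, each
number used once. Pseudonyms are `Case` + the number, zero-padded to three
digits (widened only past 999). The assignment is therefore a bijection
onto `Case001..CaseNNN`, one pseudonym per *patient* (all of a patient's
requested acquisitions share it), and any permutation is reachable —
consecutive runs with different seeds export the same data in different
orders, which is the point of the shuffle.

The shuffle seed is an explicit, required input rather than hidden
entropy. Rationale: the annotation round trip depends on re-linking
corrected labels through the very key this shuffle produced, so the draw
must be auditable and reproducible. In `deidentify` mode the key table is
written as a CSV (`Pat,Mod,Phase,Cl 1,Ns`) with the seed recorded in a
`# seed=N` comment line above the header — the comment keeps the tabular
dialect intact for plain readers while making write∘read the identity. In
`anonymize` mode nothing is written anywhere and the in-memory mapping is
discarded when the call returns; the deliberate interpretation is that an
anonymized export has *no* key at all, rather than a key filed somewhere
"safe". A request whose file is absent is reported as missing and the run
continues: cohorts legitimately contain enrolled patients with no usable
data. Extraction copies; the source tree's file set and checksums are
invariants, and tests verify them.

A request names tags, not extensions, so the extractor matches any
extension for the requested stem; more than one match is an error rather
than a guess.

## Re-integration

Corrected label volumes return named under Case pseudonyms. The inverse
key maps each back to its patient; the tag applied is, in order of
precedence: a per-file override, the file's own tag when it is already a
label code (supporting re-corrected labels), or the batch-level tag for
`IM`-tagged files. A file whose pseudonym is not in the key, or an `IM`
file with no tag to apply, is skipped and reported — manual corrections
are irreplaceable, so nothing is ever guessed, and every staged copy is
checksum-verified against its source before being reported. A staged name
that already exists is an error: one slot per label per image, no silent
versioning. Staged files then go through the ordinary structuring step,
which completes the loop by filing each label beside its originating
image.

## Segmentation metrics

With TP, FP, FN the exact voxel counts of GT ∩ Pred, Pred \ GT, and
GT \ Pred, all three metrics share the denominator |GT| + |Pred|
= 2·TP + FP + FN:

    DSC = 2·TP / (|GT| + |Pred|)      OS = 2·FP / (...)      US = 2·FN / (...)

so OS + US = 2·(1 − DSC) exactly; the implementation asserts this identity
(tolerance 1e−12) on every pair it evaluates. DSC ∈ [0, 1]; OS and US ∈
[0, 2], reaching 2 when one mask is empty and the other is not. The
cohort-level summary is the unweighted arithmetic mean of per-case values.

Conventions for degenerate inputs: both masks empty → DSC = 1, OS = US = 0
(perfect agreement on absence); exactly one empty → DSC = 0. These are
documented and test-pinned; other packages differ (some return NaN), so
comparisons across tools should check this case.

Volumes are binarized at value > 0 on load; multi-label files must be
split into one file per structure upstream, matching the
one-file-per-structure dataset layout. Complements are taken within the
image grid, which is immaterial to the results since GT̄ ∩ Pred =
Pred \ GT. Label fusion is element-wise: union mode is addition clipped at
1; multi-label mode assigns integer label i+1 to mask i and requires an
explicit priority order whenever masks overlap (later in priority wins).

The metric implementation is vectorized; its oracle in the test suite is a
deliberately independent pure-Python triple-loop voxel counter, and the
two agree to 1e−12 over a thousand seeded random pairs.

## Synthetic generators

The generators emulate the *shape* of a liver-surgery CT/MR cohort:
patients `H001..`, acquisitions `CT001`/`MR001`, phases such as `Porto`
and `T1`, tags `IM`/`LP`/`HV` by default, whole-patient dropout for
enrolled patients without usable data, and clinical tables mixing
numeric, categorical, and empty cells. Volumes are tiny (8³ voxels by
default, ≤32³ in tests) with an identity affine and random integer
payloads — big enough to move, copy, hash, and read back, small enough
that the whole workflow runs in seconds. Problem sizes used by the tests
and the acceptance script (50 patients / 400 files for structuring, 100
patients for pseudonymization, 1000 mask pairs for the metric oracle) were
chosen as the smallest sizes at which the counting invariants are
meaningful at scale.

What the generators do **not** emulate: anatomically plausible organ or
vessel shapes, realistic intensity distributions, scanner metadata,
inter-rater variability in labels, or DICOM provenance. Passing tests
therefore demonstrate the bookkeeping — placement, conservation,
leak-freedom, round-trip integrity, metric arithmetic — not segmentation
quality on real images, and published cohort-level metric values are not
reproducible from synthetic data.

Mask pairs are generated with *exact* prescribed confusion counts by
drawing TP + FP + FN distinct voxel positions without replacement and
assigning them to both/prediction-only/ground-truth-only, so every metric
value is known in closed form from three integers.

All generation flows from `numpy.random.default_rng(seed)`; a fixed spec
and seed reproduce a byte-identical tree (NIfTI gzip output is
deterministic).

## Known limitations

- The structuring step is not transactional: a collision under the
  `error` policy aborts mid-batch with the partial report in the error
  message; already-moved files stay moved.
- Pseudonymization is ID replacement only. It makes no cryptographic
  guarantee, does not touch voxel data (no face/defacing concerns for
  abdominal volumes, but the caveat stands), and does not assess
  re-identification risk from clinical attributes.
- The request dialect covers images and labels, not clinical JSONs.
- Case-sensitivity of phase/tag tokens means `Porto` and `porto` create
  distinct directories; upstream naming discipline is assumed.
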