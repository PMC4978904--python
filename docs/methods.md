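# Methods

## Site model and coordinate conventions

A CRISPR target site is a protospacer of `spacer_length` bp (default
20, the canonical guide length; 21–23 are in routine use for SaCas9 and
configurable per class) immediately 5′ of a PAM match *on the targeted
strand*. All coordinates are forward-strand, 0-based, half-open (the
BED convention). A reverse-strand match found on the reverse complement
at `[a, b)` maps to forward coordinates `[L-b, L-a)`; on `+` the PAM
starts where the protospacer ends, on `−` the forward-coordinate PAM
interval ends where the protospacer starts.

Choices that were genuinely open:

- **Ambiguous bases.** A genomic `N` matches no pattern position,
  including pattern `N`: an ambiguous assembly base is not a designable
  target. Sites whose protospacer or PAM window contains `N` are
  suppressed.
- **Record edges.** Sites without full spacer room are dropped, not
  truncated — a 20 bp guide cannot be designed against a 12 bp
  protospacer.
- **BED span.** The emitted interval covers the protospacer+PAM union
  by default (`bed_span = union`), because exon intersection concerns
  the whole editable locus; `bed_span = pam` preserves the PAM-only
  reading.
- **No deduplication.** Overlapping and dyad-symmetric sites are all
  reported; a palindromic double-match at one locus is two sites, and
  the density model counts it the same way.
- Soft-masked (lowercase) input is uppercased and treated like any
  other sequence; no masking rule is applied.

Scanning is regex-based (per-position character classes over
`{A,C,G,T}`, a lookahead so overlapping matches are all found), run on
the forward sequence and its reverse complement. Tests hold it equal to
an independent naive sliding-window oracle on hundreds of random
sequences, including `N`-bearing and edge cases.

## Exon intersection

Intersection uses an interval tree per record; the contract (verified
against an O(sites × exons) brute force) is purely set-theoretic, so
the data structure is an implementation detail. `any_overlap` (≥ 1 bp
of the union interval overlapping ≥ 1 exon) is the default reading of
"sites in exons"; `full_containment` supports strict guide-in-exon
design. Exon strand is recorded but ignored — a cut on either strand
disrupts an exon. Duplicate/overlapping exons are not merged for
per-site listings, but the exon-kb denominator in the availability
summary uses merged coverage so overlap does not inflate density.

## Density model

Bases are modelled i.i.d. with composition `(pA, pC, pG, pT)` (uniform
by default; `composition = empirical` estimates it from the scanned
genome, N's excluded). Per-strand match probability is the product over
pattern positions of the allowed-set probability mass; the both-strand
rate is twice that and the expected spacing its reciprocal. Under
uniform composition: NGG and NGA 8 bp, NNGRRN 8 bp, NNGRRT 32 bp,
NNNRRN 2 bp, NNNRRT 8 bp.

Two deliberate approximations, both documented rather than corrected:

- **Edge effects** (`L − k + 1` windows per strand, and spacer room,
  versus `L`) are ignored; the bias is O(k/L), irrelevant at megabase
  scale.
- **Overlapping-occurrence correlation** is ignored in the z
  diagnostic, which treats the both-strand count as Poisson with mean
  `rate × scanned_bp`. For loose patterns (NNNRRN is effectively an RR
  dinucleotide constraint) occurrence overlap inflates the true count
  variance somewhat, so z is mildly anti-conservative there; it is a
  diagnostic with threshold |z| ≤ 3–4, not a calibrated test. Exact
  overlapping-word statistics (correlation polynomials) and Markov
  composition models are out of scope.

Verification scales: the closed forms are checked against a seeded
1 Mb uniform genome for all six classes (|z| ≤ 4) and against a seeded
10 Mb genome for NNGRRT (observed spacing within 3 binomial standard
errors of 32 bp, ≈ ±0.17 bp at that size). These sizes make the checks
statistically sharp while keeping the default suite in tens of seconds.

## Guide oligo design

The transcription template is assembled by overlap PCR: forward oligo =
T7 promoter + spacer + first `overlap_fwd` scaffold bases; reverse
oligo = reverse complement of the last `rev_len` scaffold bases
(defaults 20/20, minimum 15 bp annealing enforced). T7 initiation
requires 5′ G's (default 2); the handling mode is configurable —
`prepend` (default: add only the missing G's, lengthening the spacer),
`substitute` (replace the first bases, keeping length but mismatching
the genome), or `reject`. Scaffold sequences are required configuration
inputs, never hard-coded: Sp- and Sa-family scaffolds differ, and a
silently wrong default would be worse than an error. Warnings flag
spacer GC outside [0.30, 0.80] and homopolymer runs ≥ 5 nt. No
on-target efficiency or off-target scoring is attempted.

## Indel calling

Alleles are globally aligned to the reference amplicon with Biopython's
`PairwiseAligner` (match +1, mismatch −1, gap open −5, gap extend −1;
the open score applies to the first gap column, extend to each further
column). Maximal gap runs become events: allele-row gaps are deletions,
reference-row gaps insertions carrying the inserted bases. Events are
then left-aligned through repeat context (the VCF normalization), which
also makes the caller insensitive to the aligner's internal tie-breaks.
Substitutions are counted but are not events.

A property worth stating precisely: exact event recovery is only
guaranteed when events are separated by at least twice the maximal gap
span. Under this affine scoring, a deletion and an insertion planted
close together can be *optimally* realigned as smaller gaps plus chance
mismatches — the planted representation is then genuinely not the
best-scoring alignment, and no aligner at these parameters can return
it. The synthetic-allele generators and the recovery tests therefore
use ≥ 50 bp separation for indels up to 25 bp. Net length change is
recovered exactly in all cases regardless (it is fixed by the sequence
lengths). The independent oracle in the tests is a hand-written Gotoh
DP compared on alignment score.

The allele report groups identical event lists, orders groups by
ascending net change, renders the reference with `-` for deleted bases
and lowercase letters for insertions, and appends `[×N]` multiplicities
— the standard figure format for Sanger-genotyped founder alleles.

## T7E1 quantification

`cleaved_fraction = Σcleaved / (uncut + Σcleaved)` from band
intensities. Assuming mutant and wild-type strands reanneal at random,
heteroduplex fraction `f = 1 − (1−p)²`, inverted as
`p = 1 − sqrt(1 − f)`. Both numbers are reported because published
indel frequencies vary in whether they apply the correction. Boundary
`f = 1` maps to `p = 1`; zero total intensity is an error. Gel-image
quantification and trace deconvolution are out of scope.

## Synthetic data

Generators emit i.i.d. genomes (`syn1..synN`), uniformly placed exons,
planted concrete PAM matches (degenerate positions sampled uniformly
from allowed sets; the spacer region is rewritten N-free so the planted
site is scannable by construction), and mutant alleles with a truth
table. A single integer seed drives each generator through NumPy's
`default_rng`; determinism is a per-generator contract, not a
cross-version bit-stream guarantee, and tests assert statistical
properties or within-run equality. The generators deliberately omit
repeats, isochores, GC skew, and real exon structure: green tests show
the computation is correct under the stated null model, not that real
genomes behave like it (zebrafish, for instance, is AT-rich, which
stretches the NNGRRT spacing above 32 bp — the `empirical` composition
mode reports, rather than asserts, that shift).

## Pipeline

`pamscape run` executes scan → annotate → density from a `key = value`
config. Outputs (per-class BED, annotated BED, summary and density
TSVs) are written atomically (temp file + rename) and checksummed into
`manifest.tsv`; a stage failure leaves earlier stages' outputs intact
and flagged in the manifest. Exit codes: 2 missing input, 3 parse
failure, 4 internal stage failure. Reruns on identical inputs are
byte-identical, manifest included.
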