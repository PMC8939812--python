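# Methods

This note records the scientific model behind `obpscan`, the defaults
and why they were chosen, and what the test battery does and does not
demonstrate.

## Motif model of OBP subclasses

Insect odorant-binding proteins keep a scaffold of conserved cysteines
whose pairwise spacings diagnose the subclass. In every subclass the
C2–C3 gap is exactly three residues and the C5–C6 gap exactly eight;
the remaining gaps vary by class. plus-C OBPs carry two extra
cysteines (C4a between C4 and C5, C6a after C6) and a conserved
proline immediately following C6. The three class definitions are
encoded as ScanProsite-dialect patterns (literal residues plus
`x(m,n)` wildcard runs); minus-C OBPs have no defining pattern and are
deliberately *not* called — a protein matching nothing is labelled
`none`, never minus-C.

### Scanner semantics

* **Substring search, all matches.** A motif may sit anywhere in the
  protein, and every distinct (start, end, anchor-assignment) triple
  is enumerated. Public descriptions of pattern scanning do not fix an
  overlap convention, so the scanner reports the superset and lets
  classification require "at least one match"; the canonical match
  recorded per protein is the leftmost-then-shortest one, which is
  deterministic and independent of input order.
* **Wildcards match anything** — including C, P and the unknown
  residue X. A *literal* anchor never matches X: anchors are the
  conserved-cysteine evidence, and an unknown residue cannot supply it.
* **Algorithm.** Backtracking over wildcard lengths guided by a
  reachability table (position p can complete the pattern suffix i)
  computed once per (pattern, sequence); every explored branch leads to
  a reported match, so the cost is polynomial in sequence length and
  pattern size plus output size. Equivalence with a regex-based
  brute-force substring oracle is asserted on >1,000 random cases.
* No PROSITE termini operators (`<`, `>`) or character classes are
  supported; the subclass motifs do not use them.

### Classification precedence

Classic's wide ranges contain most of atypical's (e.g. first gap
26–27 ⊂ 15–39), so a protein can satisfy both frames. The caller
assigns the highest-precedence matching class with the default order
**plus-C > atypical > classic** — most-constrained first; the reverse
order would make atypical unreachable inside the overlap region. The
original annotation study does not state its tie-break, so this is a
genuine design choice; it is configurable
(`ObpMotifClassifier(precedence=…)`, `--precedence` on the CLI) and
every annotation records *all* classes matched so a discrepancy table
can be derived.

PBP/GOBP (PF01395) domain support, when a domain-hit table is
supplied, is annotated but **never gates** OBP inclusion: plus-C
members routinely score poorly against the PBP/GOBP model yet carry a
complete motif.

## OR screening

ORs are retained iff they carry a 7tm_6 (PF02949) hit with e-value ≤
1e-3 (configurable); hits covering less than half the protein flag
the entry `partial` (fragment) without excluding it, since published
receptor catalogs retain short fragments. Redundancy removal
interprets "100 % sequence identity" as full-length exact string
equality, keeping the first record seen — unambiguous, idempotent and
order-stable; the alternative (alignment-local 100 % identity) is
noted but not used. The Kyte–Doolittle hydropathy segment count
(window 19, threshold 1.6, runs closer than half a window merged) is
advisory only and never filters.

## Physicochemistry

Molecular weight is the sum of ExPASy average residue masses plus one
water (18.0153 Da); ambiguous residues are a hard error unless a mean
residue mass is explicitly allowed. The isoelectric point uses the
Bjellqvist pKa set exactly as the ExPASy ProtParam tool applies it:
side chains D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0;
generic termini 7.5 (N) and 3.55 (C); **residue-specific N-terminal**
pKas (A 7.59, M 7.00, S 6.93, P 8.36, T 6.82, V 7.44, E 7.70) and
**residue-specific C-terminal** pKas for terminal D (4.55) and E
(4.75). The net charge is the Henderson–Hasselbalch sum over all
groups; it is strictly decreasing in pH, so bisection on [0, 14]
(default tolerance 1e-3 pH units) finds the unique root. Agreement is
asserted against a 1e-4 pH-grid argmin (within 2e-3) and against
Biopython's independent ProtParam implementation.

Display follows the two published table conventions: OBP catalogs
print integer Da and one-decimal pI; OR catalogs print kDa to three
decimals and two-decimal pI; rounding is half-up and applied only at
the display layer.

## Catalog conventions

* **Naming** walks chromosomes in karyotype order X < 2 < 3 <
  unplaced, then locus start, then source id; members are numbered
  1..N with unplaced entries last. The chromosome label "1" is ranked
  with X (assemblies disagree on whether the sex chromosome is called
  X or 1).
* **Clusters** are single-linkage chains of consecutive genes whose
  inter-gene gap (next start − previous end) is at most `max_gap_bp`;
  no published threshold exists, so the default is 100 kb and the CLI
  requires it explicitly in strict usage.
* **ORFs** require an ATG start and an in-frame stop (open-ended runs
  only behind `--allow-open-ended`), default minimum 150 nt, both
  strands, standard genetic code, N-containing codons translated as X;
  minus-strand ORFs are reported in forward-strand coordinates. These
  are ORFfinder-like defaults, stated here as the package's own
  choices.

## Synthetic data: what it emulates and what it does not

Generators produce proteomes where the truth is known by construction:
planted OBPs are cysteine scaffolds with gaps drawn uniformly from one
class's ranges, embedded in cysteine-free random flanks so the planted
anchors are the only cysteines. Classic-planted gap vectors that would
also satisfy the higher-precedence atypical ranges are resampled, so
exact recovery under the default precedence is a *property of the
generator*, matching its role of providing unambiguous ground truth.
Decoys are either cysteine-free or carry a six-cysteine scaffold with
a C2–C3 gap of 4–6 (no class allows that), and each decoy is verified
against all three patterns before emission. OR sets plant 7tm_6 hits
covering ≥ 50 % of each receptor-like record; duplicates are exact
copies inheriting the source's domain status, which exercises the
filter-before-dedupe ordering. Locus generation realizes a requested
cluster layout exactly, separating everything else by far more than
the clustering threshold. All randomness derives from a single integer
seed with fixed-order alphabets, so outputs are byte-identical across
platforms.

The generator deliberately does **not** emulate: signal peptides,
realistic amino-acid composition (background is uniform over the 19
non-C residues by default; configurable), homologous sequence families
or phylogenetic structure, BLAST score distributions, or borderline
domain hits. Passing the recovery tests therefore shows the motif
grammar, precedence logic and bookkeeping are correct — not that the
motif definitions themselves capture every real OBP, which is a
property of the published motif ranges, not of this implementation.

An `adversarial` generator mode plants extra cysteines inside wildcard
gaps to stress the all-matches scanner; it is excluded from recovery
tests because extra cysteines can legitimately create
higher-precedence matches.

## Problem sizes and numerical choices

The test battery and the acceptance script use: 1,000 random
(sequence ≤ 60, pattern ≤ 4 literals) scanner-oracle cases; 200 random
peptides (≤ 100 residues) for the pI grid comparison; planted
proteomes up to 200 OBPs plus 40 decoys; a 45-receptor OR set with 5
duplicates and 5 undomained backgrounds; 30 genes with one 8-member
cluster. These sizes exercise every code path while keeping a full
run in seconds. Ties in the canonical match are broken by (start,
end, anchor positions); catalog rows sort by numeric name suffix;
degenerate inputs (empty FASTA, empty hit tables, sequences shorter
than the hydropathy window) return empty results or `None` rather
than raising, except where the contract demands an error (duplicate
ids, malformed coordinates, ambiguous residues in MW).

## Known limitations

* The supplementary per-protein sequence sets of the original
  *An. stephensi* study are not redistributable inside this package,
  so the packaged reference catalogs carry the *published* per-gene
  values (names, accessions, subclass, chromosome, MW, pI) and
  sequence-level reproduction is demonstrated on synthetic proteomes
  at the published composition. Running the real proteome end-to-end
  (`identify-obps` on a RefSeq protein FASTA with a Pfam domain table
  and GFF) is fully supported but requires those external inputs.
* BLASTp and hmmscan are consumed as tabular files, never executed.
* The published prose reports an OBP pI range of 4.2–8.9 while its own
  table lists one member at 9.3; the package reports computed values
  and does not reconcile that inconsistency.
* Multiple sequence alignment, phylogeny, synteny and figure rendering
  beyond a basic chromosome map are out of scope.
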