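# Methods

## Problem and model

Adenoviruses transcribe a compact double-stranded DNA genome (~34 kb) from
both strands in temporally staged cassettes: early genes (E1–E4), the
intermediate genes IX and IVa2, and late genes (L1–L5) that all initiate at
the major late promoter (MLP) and receive a three-exon tripartite leader by
splicing. A single genomic region therefore yields many isoforms, several
ORFs can share one transcript body, and the protein a transcript produces is
decided largely by which start codon comes first after splicing.

The pipeline models a transcript class as a pair (junction signature,
representative ends): the ordered intron list on one strand plus clustered
5'/3' termini. Classification of a class to an ORF follows a single absolute
rule: **a transcript codes for an ORF when its 5'-most ATG is that ORF's
initiating methionine**. Kozak context is deliberately not modelled — weak
contexts are a plausible source of downstream initiation in the real system,
but modelling them would add parameters the data cannot constrain here.

Direct RNA-seq informs two structural assumptions. Reads are sequenced
3'→5' from the polyA tail, so the 3' end is trustworthy (the tail appears as
a soft-clipped A-run adjacent to the transcript's 3' end) while the 5' end
decays: a sizeable fraction of reads start at an essentially arbitrary point
inside the transcript body. The classifier therefore anchors 5' clustering
on the *modal* 5' position within a signature group — full-length reads pile
onto the true start, truncated reads smear — and joins 3' ends by single
linkage, splitting only at gaps wider than the end window, since genuine
polyA sites are far apart compared with end jitter.

## Categories

* `codes_orf` — first ATG sits exactly on a catalogued coding start
  (after junction snapping; no positional slack is given, since snapping has
  already absorbed coordinate wobble). When two catalogued ORFs share a
  coding start the feature whose expected TSS is nearest the class's 5' end
  wins, with a warning.
* `variant_bysplicing` — first ATG is an internal ATG of a catalogued ORF,
  in that ORF's annotated reading frame, and some intron of the class lands
  inside the ORF's coding region 5' of that ATG (so the annotated start was
  removed or bypassed by splicing). This generalises the precursor/mature
  protein VII mechanism — a splice into the precursor-coding region moves
  initiation to the methionine at the protease-cleavage boundary — without
  inventing unrelated variants: out-of-frame internal starts or unspliced
  classes never qualify.
* `truncated` — the class is a 3'-compatible sub-chain of a named coding
  class: its introns are a suffix of the parent's (possibly empty), its
  exons fall inside the parent's exons, its 3' end matches the parent's
  within the end window, and its 5' end lies more than a TSS window
  downstream of the parent's start. Note the ordering: the coding check runs
  first, so a 5'-shortened read that still retains the ORF's start codon is
  still `codes_orf` — under an ORF-centric rule it does code the protein.
  The truncated bin only collects classes whose start was lost.
* `none_from_list` — everything else. The empty-signature case is worth
  spelling out: an unspliced class inside a coding region is `truncated`
  only if its 3' end matches a named parent's polyA site; otherwise it stays
  `none_from_list`, because without junction evidence or a shared 3' anchor
  nothing ties it to a specific parent. (Distinguishing such transcripts
  from genuine novel ones is exactly the situation that requires an external
  BLAST, which is out of scope here — the unnamed transcript FASTA export
  exists for that purpose.)

Display names are `region_orfname` (collapsed to the bare name when region
and name coincide, e.g. `IX`); by-splicing variants strip a `pre` prefix
from the ORF label and append `_bysplicing`, so the precursor/mature pVII
pair reads `L2_preVII` / `L2_VII_bysplicing`.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `min_mapq` | 1 | — | retention floor; with `--min-mapq 0` even MAPQ-0 primaries pass |
| `tol` | 3 | nt | junction snap tolerance, both intron ends |
| `tss_window` | 50 | nt | 5'-end clustering window around the modal start |
| `end_window` | 30 | nt | 3'-end single-linkage gap threshold |
| `min_known_intron_count` | 5 | reads | raw support for a self-trained known intron |
| `min_count` | 2 | reads | below this a class is flagged low-confidence (never dropped) |
| `denominator` | retained | — | percentage denominator: all retained viral reads, or named reads only |

The windows absorb typical nanopore end raggedness; none of them is
published for the original pipeline, so all are configuration-exposed. The
known-intron set for snapping is self-trained (introns seen ≥ 5 times, with
non-maximum suppression inside the snap tolerance so snap targets are
unambiguous) because the ORF feature table carries no intron coordinates; a
user-supplied intron set can be added via configuration. Percentages use
retained viral reads as the denominator — including the `truncated` and
`none_from_list` pools as explicit rows is what makes each sample's column
sum to 100% and keeps timepoints comparable.

Ties are resolved deterministically throughout: even-length medians break
toward the strand-aware 5'-most coordinate, modal-anchor ties toward the
5'-most position, most-abundant-per-ORF ties toward the longer spliced
transcript then the 5'-most start. Clustering is order-independent
(permuting input reads yields identical classes), and the whole pipeline is
byte-deterministic given inputs, as recorded in the run manifest.

## The synthetic scenario

The generator stands in for real infected-cell dRNA-seq data and encodes the
study conditions the pipeline targets:

* 9 catalogued ORFs on a 34 kb genome: E1A and E2A-DBP (early; DBP on the
  reverse strand, spliced), IX and IVa2 (intermediate; IVa2 reverse-strand,
  spliced), and five late ORFs (pIIIa, preVII, pMu, hexon, fiber) all
  initiating at the MLP (position 5,858) behind a 41/72/90 nt tripartite
  leader with a shared donor.
* a mature-equivalent VII isoform using a deeper splice acceptor inside the
  precursor-coding region; the internal in-frame ATG at the cleavage
  boundary (codon 24) becomes its first start codon, so its protein is the
  precursor product minus the propeptide.
* two decoys: a body-truncated copy of the hexon transcript (start inside
  the CDS, shared polyA site → expected category `truncated`) and an
  unspliced transcript initiated and terminated inside the L2 coding span
  with its own 3' end (expected `none_from_list`).
* per-read noise: 3' ends jittered N(0, 8 nt) around the polyA site; 5'
  truncation with probability 0.2, uniform over the transcript body (keeping
  ≥ 50 nt); polyA tails N(60, 20) clipped at ≥ 10 nt, emitted as soft clips;
  an optional junction-wobble mode perturbs intron ends by up to ±3 nt with
  a centre-heavy distribution, for exercising junction snapping.
* weights shift early-high at 24 h to late-high at 48/72 h, with the
  precursor:mature pair fixed at 4.3 : 1 at 72 h; default depths are
  5,000 / 13,000 / 17,000 reads (roughly 175× below a real MinION run per
  timepoint, chosen so the full default pipeline completes in seconds), and
  the statistical acceptance checks use 20,000 reads per timepoint.

Construction is deterministic per seed: random background; ORF cassettes
planted as ATG + stop-free random codons + TAA (with per-codon overrides for
the cleavage-boundary architecture); canonical GT..AG contexts written at
every intron, strand-aware; then an ATG-scrub pass that assembles every
annotated isoform's spliced sequence and mutates away any ATG 5' of the
intended start (including junction-spanning ones), refusing layouts where
that would touch a planted element. Truth SAM files are emitted directly —
no aligner in the loop — so ingest can be tested for bit-exact recovery; an
optional read FASTA supports external alignment as an integration exercise.

What the generator does **not** emulate: basecalling/substitution errors,
host-cell reads, chimeric reads, internal polyA priming, coverage biases
along the transcript, or promoter-level transcriptional noise. Passing tests
therefore demonstrate the correctness of the classification logic under
realistic structural noise (truncation, end jitter, junction wobble), not
robustness to raw nanopore error profiles — on real data the aligner and its
junction handling carry that burden upstream.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; SAM (1-based) and BED
  (0-based) converted at the boundary. Reverse-strand feature coordinates
  follow the reading direction (documented in `genome.py`).
* Introns shorter than 4 nt cannot hold both dinucleotides and are flagged
  non-canonical with a sentinel motif.
* Ratios print to 1 decimal, percentages to 3 decimals; a zero-count
  denominator group yields an explicit `undefined`, not an exception.
* A sample with zero retained reads is an error naming the sample
  (percentages would be undefined).
* Empty alignment input produces empty-but-valid outputs; an absent
  reference in a SAM header is an error listing the available references.
* Chimeric-read splitting at internal polyA tracts is *not* performed: polyA
  evidence is recorded per read, reads are never split. The upstream
  pipeline this mirrors left the splitting rule unspecified, and splitting
  heuristics would change counts in ways that cannot be validated here.

## Known limitations

* The first-ATG rule is absolute; downstream initiation through leaky
  scanning or weak Kozak context is invisible to the classifier.
* Truncation calls require a 3' anchor shared with a named parent; truncated
  fragments of low-abundance parents (below the known-intron threshold, or
  absent from the sample) fall into `none_from_list`.
* Quantification is by read counting within collapsed classes — there is no
  EM-style reassignment of ambiguous reads, which is adequate for a single
  compact viral genome but would not transfer to paralog-rich transcriptomes.
* The feature table is taken as given knowledge (including temporal class);
  the pipeline does not discover ORFs or promoters.
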