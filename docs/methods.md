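# Methods

This note documents the models, conventions, defaults and numerical choices
behind `disorderdb`, and what its synthetic benchmarks do and do not show.

## Eligibility screening

Disorder predictors handle undetermined/ambiguous/unique residue codes
(B, J, O, U, X, Z) inconsistently; some truncate them, which shifts every
downstream residue position.  Any protein containing one of these codes is
therefore excluded from annotation entirely, and exported in a dedicated
exclusion table with the offending codes.  Gap (`-`) and stop (`*`)
symbols are not amino-acid codes at all: they indicate a malformed file and
raise a parse error rather than an exclusion.  Lower-case residues are
uppercased before screening.  Length-1 sequences are accepted; they simply
yield no continuous-disorder regions downstream.

Headers in the UniProt `sp|ACC|NAME ... PE=n SV=m` dialect are parsed
fully; plain headers are tolerated (accession = first token, PE recorded as
0/unknown in outputs).  Excluded proteins keep their PE information so the
exclusion list is as informative as the inclusion list.

## Score tracks and binary calls

Four per-residue tracks are attached to every protein: IUPred long mode
(I) and the three DisEMBL outputs Coils (C), Hotloops (H), REM465 (R).
Parsers accept the tools' text formats (comment lines tolerated; DisEMBL
records carry scores in COILS, REM465, HOTLOOPS column order, which the
parser maps back to the canonical C, H, R naming).  Both parsers reject
tracks whose residue count disagrees with the sequence — the alignment
guard that motivates the screening step.  Default decision thresholds are
the tools' published defaults: IUPred 0.5; DisEMBL Coils 0.43, Hotloops
0.086, REM465 0.5.  All thresholds are overridable.  A score exactly at
threshold counts as disordered by default; the tie convention is
configurable because published databases rarely state it.

### Built-in predictor

So the pipeline runs without external binaries, a windowed
charge–hydropathy classifier is included.  Over a window (default 21
residues, clipped at termini) centered on each residue it computes the
mean normalized Kyte–Doolittle hydropathy ⟨H⟩ = mean of (KD+4.5)/9 and
mean net charge ⟨q⟩ (D,E → −1; K,R → +1; H neutral), then the
FoldIndex-style margin FI = 2.785·⟨H⟩ − |⟨q⟩| − 1.151 relative to the
Uversky charge–hydropathy boundary.  The disorder score is 0.5 − FI
clipped to [0,1], threshold 0.5.  This predictor is physics-motivated but
deliberately simple; it is **not** equivalent to IUPred or DisEMBL, and
every track records its provenance (`builtin` vs `iupred`/`disembl`).

In builtin mode all four track slots are filled by this predictor at
distinct window sizes (I: 21, C: 9, H: 5, R: 41).  The different
smoothing scales make the four tracks disagree at region boundaries the
way genuinely different methods do, so DCC, agreement IDs and consensus
logic are exercised realistically; the windows are configurable.

## Consensus statistics

Per residue, the disorder classification count (DCC) is the number of the
four methods voting disordered.  The agreement ID is `O` when DCC = 0,
`NA` (no agreement) when DCC = 1, and otherwise the letters of the
agreeing methods concatenated in the fixed order I, C, H, R.  Consensus
calls use the strict all-four rule — consensus-disordered iff DCC = 4,
consensus-ordered iff DCC = 0 — and that rule (not the ≥ 2-method
agreement notion behind the agreement ID, which is stored as descriptive
metadata only) also defines the consensus track used for consensus CD
regions and consensus disorder content.  Disorder content is
100 × disordered/length per method and for the consensus.

## Continuous disorder

A CD region is a maximal run of consecutively disordered residues of
length ≥ 2 (the theoretical minimum for "continuous"); coordinates are
1-based inclusive.  No smoothing or merging of nearby regions is applied.
Per method and for the consensus track the region list, region count,
longest length CD_L and LCPL = 100·CD_L/length are recorded.  Proteins
with no CD under any method are omitted from all CD tables; when some but
not all methods find CD, the doubting methods carry an explicit `N/A`
sentinel row (never an absent row, never a zero).

## Charge patterning

Charge model: D, E negative; K, R positive; H and everything else neutral;
termini uncharged; no pH model.  FCR = (n⁺+n⁻)/N, NCPR = (n⁺−n⁻)/N.
Disorder-promoting residues are {A,R,G,Q,S,P,E,K} (configurable).  Mean
hydropathy is the average normalized Kyte–Doolittle value (KD+4.5)/9 ∈
[0,1]; the Uversky hydropathy averages width-5 sliding-window means with
edge windows clipped and averaged as-is.

κ is computed per blob size g as δ_g/δ_max,g and averaged over g ∈ {5, 6}
(stride-1 blobs).  For each blob, σ = (f⁺−f⁻)²/(f⁺+f⁻), with σ = 0 for
uncharged blobs (the 0/0 limit convention); δ is the mean of (σᵢ−σ_seq)²
over all N−g+1 blobs.  κ is undefined — exported as the explicit sentinel
`undefined`, never 0 — when the sequence has no charges, is shorter than
the largest blob, or δ_max = 0 (single-sign homopolymer of charge).  A
warning flag is set when proline content exceeds 15%, where κ is known to
be a poor descriptor.

### δ_max

δ_max is the maximum δ over rearrangements of the sequence's charge
composition.  For compositions with at most 100 000 distinct arrangements
(every sequence of length ≤ 12, and many longer charge-sparse ones) the
maximum is found by exhaustive enumeration, evaluated in vectorized
batches.  Otherwise a constructive candidate search is used.  The naive
"one block of +, one block of −" arrangement is *not* always the
maximizer: terminal residues appear in fewer blobs, so the optimum may
split the minority charge class across the two termini (e.g. `++------++`)
or interleave the neutral block between the charge blocks.  The candidate
family is therefore all arrangements of the form

    0^x0  A^a  0^x1  B^m  0^x2  A^(p−a)  0^x3

(one charge class A split into two blocks, the other class B whole,
neutrals distributed over the four gaps), enumerated completely for
sequences up to length 20 and on a coarse grid of split points for longer
ones, plus the plain block orderings.  On every composition of length
≤ 12 this reproduces the exhaustive maximum exactly (enforced by the
oracle suite).  For longer sequences it is an approximation; as a
guarantee that κ ≤ 1 regardless, the observed arrangement itself is always
admitted as a δ_max candidate.  The exhaustive/constructive switch point
is configurable.

The database stores κ (mean of per-size ratios) together with δ and δ_max
as blob-size averages of the per-size values; note the stored ratio
δ/δ_max of the averages need not equal κ exactly.

## Synthetic proteomes

The generator emulates a UniProt reference-proteome file at desk scale and
defines the package's benchmark conditions:

- 50 proteins of 60–400 residues by default; background residues drawn
  from average Swiss-Prot amino-acid frequencies, which places typical
  windows near the folded side of the charge–hydropathy boundary.
- 10% of sequences (rounded) receive 1–3 ambiguous residue codes,
  comparable to the share of partially defined sequences in a real
  reference proteome.
- PE qualifiers drawn from weights {1: 0.35, 2: 0.25, 3: 0.22, 4: 0.13,
  5: 0.05}, mimicking the experimental-evidence-dominated PE profile of
  well-studied proteomes; ~40% TrEMBL-style entries.
- Planted disordered segments (default one 30-residue rule applied with
  probability 0.6 per eligible protein) draw 65% of residues from
  {D,E,K,R} and the rest from a polar low-hydropathy fill alphabet.  The
  mixed charges largely cancel, so detection rests on hydropathy depletion
  plus charge, robustly crossing the built-in predictor's boundary.
  Segments are planted only in eligible proteins (ineligible ones never
  reach a predictor) and recorded in a truth table with 1-based inclusive
  coordinates.

What passing synthetic benchmarks shows: the plumbing is correct —
screening counts, track alignment, consensus bookkeeping, region
extraction, database integrity, and that the built-in predictor recovers
strongly charge-enriched low-hydropathy segments.  What it does not show:
predictive accuracy on real proteins (the built-in predictor is a
two-feature physics heuristic; real disorder involves composition biases
it ignores), realistic disorder-content distributions, or isoform/
redundancy structure of real proteomes.

## Database

One SQLite file, twelve tables (see the README table).  Primary keys:
`(accession, position)` for residue rows, `(accession, region_index)` for
CD rows, `accession` elsewhere, `organism` for the organisms table.  The
organisms rows carry the per-method thresholds used for the run so that
binary calls, DCC and agreement IDs can be re-derived from stored scores
alone; the validator does exactly that on a sample, alongside table-count,
key-uniqueness, row-conservation, PE-domain and referential-integrity
checks.  Scores are stored at full precision; percentages on the 0–100
scale; `N/A` and `undefined` sentinels are strings, distinguishable from
numeric zero.  PE 0 is an extension meaning "no PE tag in the header".
The writer computes everything before opening the output file and refuses
to overwrite without an explicit flag, so a failed run never leaves a
partial database.  The schema is content-compatible with the layout
described for published disorder databases of this kind, not
byte-compatible with any particular one.

## Problem sizes

Defaults keep every stage interactive on one CPU: the bundled test suite
and the acceptance script use proteomes of 12–40 proteins (about 2 000–
9 000 annotated residues), 5 generator seeds for recovery statistics, the
complete composition sweep at lengths ≤ 12 for the κ oracle, and a
100-sequence panel for the independent parameter cross-check.  All sizes
scale up linearly in sequence count; δ_max's constructive search is the
only super-linear step in protein length and is bounded by its candidate
grid.

## Known limitations

- IUPred short/structured modes and DisEMBL smoothed/peak outputs are not
  parsed; only long-mode and raw per-residue scores formats.
- The built-in predictor shares its two features (charge, hydropathy)
  with the κ/FCR parameter block, so correlations between its calls and
  those parameters on synthetic data are structural, not biological.
- δ_max is exact only in the exhaustive regime; for long sequences the
  constructive search is a documented approximation (κ remains in [0,1]).
- Per-sequence parameters only: no sliding-window κ/FCR profiles.
- No UniRef-based redundancy reduction; users combining organisms should
  handle isoform redundancy themselves.
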