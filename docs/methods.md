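# Methods

This note records the scientific and numerical choices behind the package:
what is modelled, which parameters matter, what the synthetic fixtures do
and do not emulate, and where the design was genuinely open.

## Mass conventions

Monoisotopic masses are sums of principal-isotope exact masses from the
bundled NIST/IUPAC table (`data/isotopes.tsv`; C, H, N, O, P, S). Nominal
masses are integer sums of principal mass numbers (H=1, C=12, N=14, O=16,
P=31, S=32). Positive-mode ions are M + z protons with the proton mass
constant 1.007276466 Da, which folds the electron mass into the charge
carrier; no other adduct chemistry is modelled, and average (chemical)
masses are out of scope. Full precision is kept internally; 4-decimal
rounding (half-even) happens only at presentation. With these constants
the calculated [M+3H]3+ of C115H174N28O31S2 is 836.7520 at 4 decimals.

Two small inconsistencies in published-style reporting are worth knowing
about when comparing outputs against literature values: deconvoluting an
observed m/z with the standard proton mass can differ from a printed
"neutral monoisotopic mass" by ~0.5 mDa (instrument software sometimes
uses slightly different constants), and ppm errors recomputed from
4-decimal printed m/z values can differ in the last digit from errors
computed at full precision. `deconvolute` and `ppm_error` implement the
plain definitions.

## Isotopologue fine structure

`fine_structure` enumerates heavy-isotope compositions by dynamic
programming over elements (per-element multinomial expansion, then
cross-element products). An FFT/convolution approach would be faster but
collapses the very information FT-ICR fine structure resolves — which
composition (13C1 vs 15N1 vs 33S1) carries each sub-peak — so the DP is
deliberate. Pruning uses a relative-abundance threshold (default 1e-6);
since every remaining factor of a partial product is a probability ≤ 1,
pruning partial states below the threshold never discards an isotopologue
whose final abundance would reach it. The truncated probability mass is
reported as `truncation_loss`. Aggregation into nominal M+k peaks uses
abundance-weighted centroids. Instrument peak shape and resolution are not
modelled; the output is a stick spectrum.

## The maturation rule engine

Products are defined by ordered, typed events with fixed elemental deltas
(dehydration −H2O; phosphorylation +HPO3; reduction +H2; oxidative
decarboxylation −CO2−H2 = −46.00548 Da; disulfide −H2; N,N-dimethylation
+C2H4; Aaa rearrangement and thioether crosslinking 0 Da relative to the
already-dehydrated residue). The oxidative decarboxylation delta follows
the thioenol-forming chemistry of HFCD-family flavoproteins (the AviCys
convention); reported ion spacings in this family can deviate from it by
several mDa, which we treat as measurement error rather than chemistry.

The enzyme-set → product mapping is data (`data/kin_rules.yaml`), not
code. Positional roles default to `auto` and are derived from the
precursor's own anchor motif S–[ST]–X–X–C–X{g}–T–X{4}–C:

* the Aaa site is the first S anchor (Ser-7 in the founding member);
* the retained Ser is any Ser strictly between the Thr acceptor anchor
  and the C-terminal Cys anchor (Ser-25);
* the reductase (KinJ) substrates are Ser-derived Dha strictly between
  the thiol Cys and the Thr acceptor anchors (13/16/18);
* the crosslink connectivity is thiol Cys / Thr acceptor / decarboxylated
  C-terminal Cys (11/22/27).

Whether these site selections are substrate- or enzyme-determined is not
experimentally settled; expressing them as anchor-relative structural
rules is this package's design choice. It reproduces the founding
pathway's site pattern exactly and generalises to generated kin-like
precursors, while explicit position lists in the YAML override the rules
for pathways that behave differently. Enzyme gating is also data:
elimination (KinC) requires the kinase (KinD); decarboxylation and
cyclisation require the KinH/KinI pair acting on the fully dehydrated
{C,D} substrate; N,N-dimethylation requires a free N-terminus (prior
KinE/F proteolysis). The kinase-only product is reported as the
monophosphorylated species at the first dehydratable position because the
kinase is processive from the N-terminus and the elimination partner is
absent; `processive_series` enumerates the full +HPO3/−H3PO4 intermediate
ladder.

Variant prediction inherits positional roles from the parent sequence, so
substitutions that destroy an anchor (e.g. removing the thiol Cys) keep
the rest of the rule set intact: dehydration proceeds, decarboxylation and
cyclisation are suppressed. The dual-product rule — when every
dehydratable Thr upstream of the Aaa site is substituted away, the Aaa-site
Ser is phosphorylated inefficiently and a partially dehydrated product
co-accumulates — emits both products with a fixed 0.5/0.5 ratio as
metadata; no kinetic model is implied.

GluC digestion cleaves C-terminal to Glu. Accessibility is caller-masked
because modification state controls it: on the dehydrated core the
internal Glu site is shielded unless the downstream structure is
disrupted. Fragment formulas are sums of per-position effective
compositions (genetic residue + the deltas of events attributed to that
position) plus water; multi-site events (disulfide, crosslink) are
attributed to their first site, so a fragment carries their delta iff it
contains that site.

The bundled demo precursor (`kina_like_precursor`) is synthetic: all
chemistry-bearing residue identities are fixed by the pathway logic and
the remaining positions carry a fixed arbitrary arrangement of the residue
inventory that closes the mature product's formula to C115H174N28O31S2.
Predictions that depend only on masses, composition or anchors are
therefore exact; residue-order-specific fragment assignments at the
unconstrained positions are not meaningful for this demo sequence, and
users with the real precursor sequence should supply it as FASTA with a
`leader_len=` header tag.

## MS matching

Fragment conventions: b_i = Σ residues(1..i) + z protons; y_j = Σ last j
residues + H2O + z protons; c = b + NH3 and z = y − NH3 for ECD-type
spectra. With an intact bis-thioether macrocycle, backbone cleavage inside
the crosslinked span cannot separate fragments; `suppress` mode (default)
omits those ions and `labile` mode emits them, modelling thioether C–S
scission accompanying backbone cleavage. Both behaviours are needed
because crosslinked peptides both resist fragmentation inside the ring and
still produce some ring-spanning ions; which C–S bond breaks is not
asserted — labile mode emits candidates.

Matching is greedy nearest-match within a ppm tolerance (default 5 ppm,
the FT-ICR regime), ties broken toward smaller |Δppm| then lower charge,
each ion and each peak used at most once. Intensity is carried and
reported but never used in matching decisions — no intensity model is
available. Sequence-tag inference reads consecutive single-ladder peak
deltas against the residue table (standard residues plus
Dha/Dhb/Aaa/methyl-Aaa/Abu/phospho-Ser/Thr); residues sharing one
composition (Dha vs Aaa at 69.0215; Dhb vs methyl-Aaa at 83.0371) are
reported as an isomer set, since MS alone cannot split them.

## Genome mining

Short ORFs (default 30–120 aa, the RiPP precursor regime) are found by a
six-frame scan with actinobacterial start codons ATG/GTG/TTG; for each
in-frame stop, the longest ORF within bounds is reported, with 0-based
half-open forward-strand coordinates that include the stop codon. Motif
scanning enumerates the anchor template over an inner gap range g ∈ [6,16]
(the founding member has g = 10; homologue spacings are not otherwise
constrained), allowing overlapping hits.

Co-occurrence calls align every ORF of plausible enzyme length (default
100–600 aa) within ±10 kb of a motif-bearing short ORF against reference
proteins for each role, using Smith–Waterman local alignment (BLOSUM62,
gap open 10 / extend 1) through Biopython's PairwiseAligner. A role is
called present when the best score reaches `score_min`, default 100: at
these protein lengths unrelated sequences reach local scores of about 65,
while genuine homologues (even at 5% substitution) score in the hundreds
to thousands, so 100 separates the two regimes with a wide margin. "Close
proximity" is not a quantified notion in this family; the ±10 kb window is
a free parameter. Profile HMMs, genome annotation and sequence-similarity
networks are out of scope — per-role best-hit calls are all the survey
needs.

## NOE filtering

The effective distance of a trajectory is ⟨r⁻⁶⟩^(−1/6) over post-burn-in
frames (default burn-in 10%), reflecting the r⁻⁶ dependence of NOE
intensity; it never exceeds the arithmetic mean and is scale-equivariant.
A monitor is satisfied when the effective distance lies inside its bounds
— 1.8–5.0 Å for general monitors, 4.0–5.0 Å for weak long-range monitors.
Since published workflows rarely state their satisfaction criterion, an
alternative fraction-of-frames-in-bounds mode (default q = 0.8) is also
provided; the r⁻⁶ mode is the default. Candidates are ranked by
(satisfied monitors desc, total violation asc, candidate id) — the id
tie-break makes ranking deterministic. The MD engine itself, 3-D model
building and NOE back-calculation are out of scope: trajectories arrive
as per-frame distance tables.

## Synthetic data: what it does and does not show

All generators are pure functions of a seeded config and return their
ground truth alongside the fixture. They emulate: the anchor layout and
Thr-rich N-terminus (3–5 Thr among the first eight core positions) of
kin-like cores; GC-rich genomes (72% GC filler) with colinearly planted,
stop-codon-insulated genes reverse-translated with a fixed
most-frequent-codon *Streptomyces* table and 5% amino-acid substitutions
in the planted homologues; FT-ICR-like peak lists with Gaussian
ppm-relative jitter (default sd 3 ppm) and uniform decoys; and Gaussian
distance trajectories (default sd 0.1 Å, 200 frames) around planted
means.

They do not emulate: isotope envelopes or intensity structure in spectra
(monoisotopic sticks only), operons/overlapping genes or reverse-strand
gene placement, sequencing error, correlated MD dynamics, or realistic
leader-peptide sequence diversity. Passing tests on these fixtures
therefore demonstrate the correctness of the bookkeeping, matching and
detection logic under controlled noise — not performance on raw instrument
or genome data.

Test problem sizes: random-formula isotope checks run at ≤ 50 atoms
against an exhaustive atom-by-atom convolution oracle; alignment checks at
≤ 50 residues against a naive Gotoh DP oracle; planted-BGC recovery over
20 seeds on ~9 kb contigs; NOE classification over 50 seeds at sd =
0.05 μ. These sizes were chosen to exercise every code path with exact
oracles while keeping the suite fast.

## Known limitations

* The MAbi acceptor position follows the Dhb-22/Abu(S2)-22 connectivity;
  an alternative Dhb-24 attachment reported once in the source family is
  not modelled.
* The disulfide delta is attributed to the first Cys of the pair, so a
  digest fragment containing only the second Cys of a bridged pair would
  carry the wrong −H2 attribution; in practice bridged fragments are
  evaluated whole.
* Sequence tags assume a single-charge, single-series ladder; mixed-series
  spectra need ladder separation upstream.
* The kinase-only state is reported as the monophosphorylated species;
  distributions over phosphointermediates are not modelled.
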