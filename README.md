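# bithionin

Inference tools for **beta-bithionin RiPP pathways** — the family of
ribosomally synthesized and post-translationally modified peptides founded
by kintamdin, a *Streptomyces* macrocyclic peptide carrying a bis-thioether
crosslink (MAbi), a beta-enamino acid residue (Aaa), d-Ala residues and an
N,N-dimethylated N-terminus.

The package is for natural-product and biosynthesis researchers who need to
connect a precursor gene to observed high-resolution MS data. It covers the
full inference chain:

* **chem_core** — elemental-formula arithmetic, monoisotopic/nominal
  masses, protonated-ion m/z, charge deconvolution, ppm errors.
* **isotopes** — isotopologue fine structure (13C1 / 15N1 / 34S1 / ...)
  of ion formulas and aggregated M+k envelopes, for confirming elemental
  formulas on FT-ICR data.
* **ptm_engine** — the kin maturation rule engine: typed PTM events with
  fixed elemental deltas, enzyme-set to product mapping, core-substitution
  variant prediction, GluC digestion bookkeeping and the processive
  phosphorylation/elimination series.
* **ms_match** — crosslink-aware b/y/c/z fragment ladders, ppm peak
  matching of MGF/TSV peak lists, de novo sequence-tag inference.
* **mining** — six-frame short-ORF detection, scanning for the
  S–S/T–X–X–C–Xn–T–X4–C precursor signature motif, and Smith–Waterman
  co-occurrence calls for KinC/D/H/I enzyme homologues.
* **noe_filter** — NOE distance-restraint filtering of stereoisomer
  candidates from MD distance trajectories (r^-6 ensemble averaging).
* **synthetic_data** — deterministic generators for precursors, genomes
  with planted gene clusters, noisy spectra and distance trajectories.

## The model in brief

A kin precursor is a leader peptide (positions ..., −2, −1) fused to a
27-residue core (1..n). Maturation is modelled as ordered, typed events
with exact elemental deltas:

| event | delta | enzyme |
|---|---|---|
| phosphorylation | +HPO3 (+79.96633 Da) | KinD |
| dehydration (Ser→Dha, Thr→Dhb) | −H2O (−18.010565 Da) | KinC·KinD |
| rearrangement to Aaa (ΔZβAla) | 0 Da | KinC·KinD |
| oxidative decarboxylation (C-term Cys) | −CO2−H2 (−46.00548 Da) | KinH·KinI |
| thioether crosslink (MAbi) | 0 Da | KinH·KinI |
| reduction Dha→d-Ala | +H2 | KinJ |
| leader proteolysis | — | KinE/F |
| N,N-dimethylation | +C2H4 | KinO |

A product's formula is pure bookkeeping — precursor segment + Σ event
deltas — so every predicted ion is exact, and m/z follows
(M + z·1.007276466)/z.

## Worked example

```
$ bithionin mass --formula C115H174N28O31S2 --charge 3
C115H174N28O31S2  [M+3H]3+  m/z 836.7520
```

836.7520 is the calculated triply protonated ion of the mature peptide's
molecular formula — matching the published calculated value at 4 decimals
(observed 836.7524, Δ = 0.48 ppm by `ppm_error`).

```python
from bithionin import EnzymeSet, gluc_digest, kin_maturation, ppm_error
from bithionin.synthetic_data import kina_like_precursor

precursor = kina_like_precursor()       # synthetic, mass-consistent demo
product = kin_maturation(precursor, EnzymeSet.from_codes("C,D"))
print(product.label, product.n_dehydrations)   # 11 11

fragment = [f for f in gluc_digest(product, accessible_sites=[-6])
            if f.start == -5][0]
print(round(fragment.mz(2), 4))                # 1481.1809
print(round(ppm_error(fragment.mz(2), 1481.1782), 2))   # 1.84
```

The `{KinC, KinD}` product is the fully dehydrated linear peptide: 11
waters lost (−198 Da nominal), Ser-7 rearranged to the beta-enamino acid
Aaa, Ser-25 retained. GluC release of the core plus five leader residues
gives a doubly protonated ion within 2 ppm of the reported 1481.1782.
Variant prediction reproduces the substitution shifts exactly: T2A −12 Da,
S7T +14 Da (methyl-Aaa), and the TtoA variant yields two products 18 Da
apart in a 1:1 ratio.

The bundled demo precursor is a clearly labelled synthetic surrogate: its
chemistry-bearing positions are fixed by the pathway logic and its overall
composition closes the mature molecular formula, but the arrangement of
the unconstrained positions is arbitrary (see
`bithionin.synthetic_data.kina_like_precursor`).

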