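# Methods

## Structural model

A fatty acid is `(chain_length, double_bonds)` with carbons numbered from
the carboxyl carbon (C1) and Δd denoting a C=C between Cd and Cd+1. The
model admits any strictly increasing bond set with adjacent spacing ≥ 2
(conjugated systems are representable and flagged by the unsaturation
classifier, but no enzyme operator here produces them). Geometry
(cis/trans) is not modelled: none of the assays the package serves
distinguishes it, and all bonds are treated as cis.

The omega dialect `C:Dn-x` is expanded as positions `C − x − 3k`,
k = 0 … D−1: counting from the methyl terminus with strict methylene
interruption. This is the only expansion consistent with both the
measured elongation pairs (n-x preserved under +2 carbons) and the naming
of the Δ5 product of stearate as 18:1n-13. NMI structures are refused an
omega name rather than guessed, since the field names them Δ-style only.

## Enzyme operators and the activity fixture

Elongation appends the C2 unit at the carboxyl end, so every Δ position
shifts by +2 — the only mechanism consistent with every substrate→product
pair in the panels (e.g. 18:3n-3 Δ{9,12,15} → 20:3n-3 Δ{11,14,17}).
Front-end desaturation inserts one position, subject to the spacing-≥2
rule. The chain cap defaults to C24, the longest product any assayed
elongase produced.

The fixture (`data/activity_panels.csv`, 136 rows, 16 enzymes) transcribes
the yeast heterologous-expression assay: one row per substrate/enzyme with
a measured conversion %, the sentinel `n.d.` (below detection — kept
distinct from a measured 0.0, since a detection limit is not a zero), or
`qual` for activities evidenced only by chromatogram peaks whose
percentages were not tabulated in the main results (the MUFA elongations
by Elovl6-like C and the 18:0 → 18:1n-13 Δ5 desaturation by FadsA).
Every row is validated on load: the product must equal the operator
applied to the substrate, which caught transcription errors during
development and guards future edits.

## Pathway graph

The graph is the closure of a precursor set under *recorded* activities
only — operators are never extrapolated to unassayed substrates, so e.g.
no elongation of an NMI product is invented. An edge qualifies when its
conversion is ≥ the threshold or qualitative. The threshold defaults to
5%: in the panels this cleanly separates every activity treated as
functional (≥ 5.7%) from every trace activity treated as absent (≤ 3.9%),
and in particular keeps the 0.5%/0.1% Δ6 conversions out, which is what
makes the Δ6 pathway unavailable. Qualitative records always qualify:
the NMI-dienoic branch (16:1n-7 → 18:1n-7 → 20:1n-7 → 20:2^Δ5,13^ and
18:1n-9 → 20:1n-9 → 20:2^Δ5,11^) exists only through them, so a
threshold of 100% leaves precursors plus the qualitative MUFA-elongation
edges rather than a bare precursor set.

Default precursors are {16:1n-7, 18:1n-9, 18:2n-6, 18:3n-3}: the yeast
endogenous MUFA plus the two dietary C18 PUFA. 18:3n-6/18:4n-3 are left
to be *reached* (they are not, at the default threshold, since only Δ6
desaturation produces them). Routes are simple paths found by exhaustive
DFS (< 100 nodes makes this trivial), ordered by length then by the
enzyme-name sequence.

## Conversion statistic

`conversion % = 100 × Σ products / (substrate + Σ products)` on raw peak
areas; areas are unitless and no response-factor correction is applied.
An all-zero denominator raises instead of returning 0: a chromatogram
with neither substrate nor product is a failed assay. For iterated
elongation the cascade products (products of products recorded for the
same enzyme) present in the table all count in the numerator; the cascade
walk stops at the first acid missing from the table. Peak identification
(retention-time matching) is upstream of this package; input tables are
already identified.

## DMOX fragment model

Unit-mass integer arithmetic: anchors mz(2) = 113, mz(3) = 126, then
+14 per carbon or +12 across a double-bond-starting carbon, molecular ion
= mz(C−1) + 15. These anchors are the unique integers consistent with the
observed 222/234 and 250/262 gap pairs under the +14/+12 rule, and give
the correct nominal molecular ion for palmitic DMOX (309, C20H39NO).
A useful closed form asserted in the tests: M⁺ − 113 = 14·(C−2) − 2·B for
B double bonds.

Double bonds are only inferable within Δ[4, C−2]; structures outside this
window are declared out of model rather than guessed. Δ5 is additionally
(and in inference, primarily) signalled by the diagnostic ion at m/z 153;
the diagnostic table has that single entry and is the extension point for
further rules.

Inference enumerates every candidate bond set (≤ 6 bonds, spacing ≥ 2,
detectable window), scores each by the fraction of its predicted peaks
(ladder ∪ diagnostics ∪ M⁺) present in the spectrum at exact unit mass,
and returns the argmax; ties prefer fewer bonds, then the
lexicographically smallest set; a best score below 0.5 is reported as an
uninterpretable spectrum. Candidate ladders are precomputed per chain
length as a boolean peak matrix, so scoring is a single vector product —
this is what makes the exhaustive inversion test (every structure with
C ≤ 22, D ≤ 4) run in seconds. Intensities are ignored beyond presence,
and isotopes are not modelled: all of the evidence the method rests on is
unit-mass peak positions.

## Motif screens

Patterns are PROSITE-like: `/` alternation at a position, `X` wildcard.
The PUFA-elongase motif takes precedence on a double match (it is longer
and more specific) with the ambiguity flagged; the desaturase screen
requires all three histidine boxes with their *first occurrences* in N→C
order, with no spacing constraint. An unknown residue `X` in an input
sequence matches only wildcard positions — conservative, so an ambiguous
residue can never certify a motif. No positional (e.g. transmembrane)
context is imposed.

## Synthetic data

Generators draw everything from one `numpy.random.Generator` seeded by a
single integer, so identical configs are bit-identical.

*Proteins*: uniform-random background over the 20-letter alphabet with
the class motif(s) embedded at random positions (one histidine box per
sequence third for the desaturase class, guaranteeing N→C order),
rejection-sampled until the classifier returns exactly the requested
class without ambiguity. This makes generator/classifier agreement exact
by construction, which is the point: the screens are then tested against
an independent regex oracle, not against the generator.

*Peak tables*: the substrate+product mass is split to match the true
conversion exactly, then each area gets unit-mean log-normal noise of the
configured CV (areas are positive and detector noise multiplicative;
noiseless tables reproduce the true conversion to the last bit). The four
endogenous yeast FAMEs (16:0, 16:1n-7, 18:0, 18:1n-9) are added as
background unless they already play an assay role. The ratio estimator is
slightly biased at finite CV; the tests check |bias| < 1 point at CV 0.1
over 200 replicates, and that bias vanishes as CV → 0.

*Spectra*: predicted ladder with geometrically decaying intensities,
diagnostics and M⁺, minus seeded dropout, plus uniform noise peaks. Two
protections keep the ground truth recoverable from presence-only scoring:
(i) the diagnostic region — both flanks of every 12-u gap, the 153 ion
and M⁺ — is never dropped, because with one flank missing the widened
26-u gap admits 12+14 in either order and Δq vs Δ(q−1) becomes
information-theoretically ambiguous; (ii) noise peaks keep ≥ 3 u away
from every true ladder position, because a one-position-shifted candidate
predicts peaks exactly 2 u below true ones and a noise peak landing there
would forge an exact score tie. Under these conditions recovery on
10-noise-peak, 10%-dropout spectra is ≥ 95% (measured at 100% over 200
seeded draws in the tests).

What the synthetic data does *not* emulate: real EI fragment intensities
and rearrangement ions, retention behaviour, co-elution, detector
saturation, real sequence composition (hydrophobicity, transmembrane
segments) or homology structure. Passing these tests therefore shows the
algorithms are correct under their stated models, not that the models
capture every behaviour of instrument data.

## Problem sizes

The exhaustive suites are desk-scale by design: omega-expansion oracle
over all C ≤ 24, D ≤ 6; DMOX inversion over all structures C ≤ 22, D ≤ 4
(scored against the full ≤ 6-bond candidate space via one matrix product
per chain length); 200-replicate Monte-Carlo checks for the conversion
statistic and spectrum recovery. The whole suite runs in well under a
minute.

## Known limitations

- Conversion percentages are single measurements; no replicate structure
  or uncertainty model is attached to the fixture.
- The pathway graph is qualitative reachability, not flux: edge inclusion
  is thresholded, and competing substrates are not modelled.
- The DMOX model is unit-mass and presence-based; it cannot distinguish
  structures whose predicted peak sets coincide after heavy peak loss,
  and bonds at Δ2/Δ3 or at the methyl terminus are out of model.
- The deposited GenBank accessions can be fetched and screened
  (`pufapath.motifs.fetch_deposited_sequences`) only with network access;
  offline, the motif screens are exercised on synthetic sequences.
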