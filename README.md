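# pufapath

A toolkit for the computational side of LC-PUFA biosynthesis studies in
marine invertebrates: fatty-acid nomenclature algebra, desaturase/elongase
reaction operators, biosynthesis pathway-graph reconstruction (including
non-methylene-interrupted fatty acids), GC-FID conversion statistics,
DMOX EI-MS double-bond localization, and motif-based classification of
candidate enzyme sequences.

It was built around the enzyme complement of the sea urchin
*Hemicentrotus pulcherrimus* — 13 elongases (Elovl) and 3 front-end
desaturases (Fads) characterized by heterologous expression in yeast —
and ships that activity dataset as a validated fixture, but every piece
(parsers, operators, graph builder, spectrum model, motif screens,
synthetic-data generators) is generic and reusable.

## The science in brief

**Nomenclature.** A fatty acid is `C:D` with double bonds written either
Δ-style (counted from the carboxyl carbon: `20:2^Δ5,11^`) or omega-style
(terminal bond counted from the methyl end: `20:4n-6`). The omega name is
only defined for methylene-interrupted patterns (successive bonds spaced
three carbons); non-methylene-interrupted fatty acids (NMI-FAs) such as
`20:2^Δ5,11^` have no omega name and the library refuses to invent one.

**Enzymes.** Elongases add a C2 unit at the carboxyl end (chain +2, every
Δ position +2, n-x class preserved); front-end desaturases insert a bond
at a fixed Δ position (here Δ5, Δ6 or Δ8). A key identity used throughout:
`elongate(desaturate(fa, d)) == desaturate(elongate(fa), d + 2)`.

**Pathways.** Starting from precursors {16:1n-7, 18:1n-9, 18:2n-6,
18:3n-3}, the closure under every assayed activity with conversion ≥ 5%
(or qualitative chromatogram evidence) yields the species' biosynthetic
map: the Δ8 pathway to arachidonic (elongation → Δ8 → Δ5 from 18:2n-6)
and eicosapentaenoic acid, four C20 NMI-FAs, and no route to DHA (neither
the Δ6 pathway nor the Sprecher pathway is available).

**GC quantification.** conversion % = 100 × Σ product areas /
(substrate area + Σ product areas), with iterated elongation products
counted in the numerator.

**DMOX MS.** The 4,4-dimethyloxazoline derivative fragments into a carbon
ladder: m/z 113 and 126 anchor the 2- and 3-carbon ions, each further
carbon adds 14 u — or 12 u across a carbon starting a double bond — and
the molecular ion sits 15 u above the last ladder ion. A 12-u gap between
the (n−1)- and n-carbon ions localizes a bond at Δn; Δ5 is read from the
diagnostic ion at m/z 153. Inference enumerates candidate bond sets and
scores predicted-peak presence.

**Motifs.** S/MUFA vs PUFA elongase subfamilies are recognized by
`H-W/T-X-H-H` vs `Q/H-X-T/S-X-L-H-X-X-H-H`; desaturases by the three
histidine boxes `H-X-X-X-H`, `H-X-X-H-H`, `Q-X-X-H-H` in N→C order.

## Worked example

```pycon
>>> from pufapath import *
>>> fa = parse_shorthand("20:4n-6")
>>> fa.double_bonds
(5, 8, 11, 14)
>>> to_omega(apply_desaturation(parse_shorthand("18:0"), 5))
'18:1n-13'
>>> g = build_graph()          # packaged panels, 5% threshold
>>> for r in enumerate_routes(g, parse_shorthand("20:5n-3")):
...     print(" -> ".join(s.activity_label for s in r.steps))
C18→C20 -> Δ8 -> Δ5
>>> s = predict_series(parse_shorthand("20:2^Δ5,11^"))
>>> s.mz_of(10), s.mz_of(11), diagnostic_ions(parse_shorthand("20:2^Δ5,11^"))
(222, 234, {5: 153})
```

The route printout is the Δ8 pathway: 18:3n-3 is elongated to 20:3n-3,
Δ8-desaturated to 20:4n-3, then Δ5-desaturated to EPA. The 222/234 pair
is the 12-u ladder gap that places a double bond at Δ11, and 153 is the
Δ5 diagnostic ion.

The same functionality is exposed on the command line:

```sh
pufapath convert 20:4n-6                    # -> 20:4^Δ5,8,11,14^
pufapath dmox predict "20:2^Δ5,13^"         # ladder incl. 250/262 gap
pufapath reproduce-figure5 --out out/       # pathway map + C20 inventory
pufapath simulate proteins --seed 1 --out prot.fasta
pufapath screen --in prot.fasta --out classes.csv
```

`reproduce-figure5` reports 4 C20 NMI-FAs and 6 C20 methylene-interrupted
PUFA reachable from the default precursors.

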