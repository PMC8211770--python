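# Methods

This note records the scientific model behind `olimp`, the defaults and
why they were chosen, and what the synthetic-data tests do and do not
demonstrate about real spectra.

## Grammar and composition model

An XGO is an ordered string of sidechain codes, one per backbone
glucosyl unit, reducing end last.  The shipped alphabet is
G, X, L, F, S, D, E, B, Y, P with the residue contents listed in
`data/sidechains.tsv`; it is extensible through the same table (the Q
sidechain, reported in the literature as carrying galactose plus
galacturonic acid with further decoration, is deliberately not shipped
because its full residue content is not settled — add it via
configuration when needed).

Three identity collapses are intentional, because single-stage MS cannot
resolve them:

* **Epimers.** Hex means Glc or Gal; HexA means GlcA or GalA.  Reports
  say Hex/HexA; which epimer is meant follows from the code in prose
  only.
* **Mass-degenerate letters.** S, D and B all contain two pentoses.
  They remain distinct grammar symbols, and annotation reports
  degeneracy groups instead of picking one.
* **O-acetylation.** Acetyl position is not mass-resolvable, so a
  structure carries an integer `acetyl_count` rendered as a `+nAc`
  suffix (`LPGGG+1Ac`).

The reducing end is the *last* character: `XXXG` has its unsubstituted
glucose at the reducing end, matching the field's string orientation.

The display representative of an isomer set puts the more decorated
sidechains nearest the reducing-end glucose (the common drawing
convention), implemented as the lexicographically smallest
decoration-weight tuple with the code string as tie-break.  When a
composition is realisable at several backbone lengths, the overall
representative minimises the number of unsubstituted (G) units first —
endo-xyloglucanase products rarely retain internal bare glucoses, so
Hex4·Pent2 is presented as XLG rather than XXGG.

## Mass conventions and adducts

Monoisotopic, average and nominal residue-mass tables are all
first-class, and every report states which one produced a number.  This
matters because published integer m/z values mix conventions: the
fucosylated/uronic assignments (1099, 1393, 1555, 1129, 1423, …) are
monoisotopic [M+Na]+ *truncated* to integer, while the sparsely branched
series (1146, 1322, 1440, 1616) is average-mass [M+Na]+ rounded to
*nearest*.  Both behaviours are pinned in the acceptance tests.

Charge is fixed at +1 (MALDI of neutral glycans), the default cation is
Na+, and K+, H+ and the di-sodiated acid form [M+2Na−H]+ are available.
The [M+2Na−H]+ adduct sits 21.98 Da above [M+Na]+, which makes it a
plausible reading of a peak ~22 Da above an acidic XGO (e.g. 1445 vs
1423); such peaks are reported as unassigned candidates, not asserted
identifications.  The electron mass is ignored (≈5·10⁻⁴ Da, far below
every tolerance used).  Isotope patterns, peak shapes and multiple
charging are out of scope: inputs are centroid peak lists.

## Candidate enumeration

Composition enumeration is an exhaustive scan over count vectors within
bounds Hex ≤ 10, Pent ≤ 6, dHex ≤ 2, HexA ≤ 3, Ac ≤ 2 (configurable) —
generous for XGO pools of 2–6 backbone units while keeping the search
space below 3000 vectors, so brute force is exact and fast.  The default
tolerance is ±0.5 Da, matching integer-reported MALDI peaks.  Queries
outside the m/z 200–4000 acquisition window are answered but flagged.
Structure enumeration assigns codes to backbone positions over a default
backbone range of 2–6 units, optionally pinning the reducing end to G
(endo-glucanase products).

### Near-degenerate compositions

Distinct count vectors can be nearly or exactly isobaric.  The two
practically relevant cases, found by scanning all in-bounds vectors:

* Pent + HexA vs Hex + dHex differ by 0.0365 Da — a xylose/uronic pair
  is almost isobaric with a hexose/fucose pair (e.g. Hex5·Pent3·HexA1 vs
  Hex6·Pent2·dHex1 at m/z ~1423);
* 4 Pent and 3 Hex + 1 Ac are the *same* molecular formula (C20H32O16).

Mass error below this scale therefore carries no information, which
shapes the ranking below.

## Enzyme models

Digestion is purely structural rewriting — no kinetics, concentrations
or pH; its role is to rationalise observed oligosaccharide pools.

* **XEG-type endo-xyloglucanase** cleaves the backbone bond after an
  unsubstituted glucose; **XcXGHA-type** cleaves between two substituted
  units.  Rules are positional predicates on adjacent codes; a
  configurable minimum product length (default 1) stands in for subsite
  occupancy.  Both rule sets are available because observed XXG-type
  cores can arise under either reading.
* **α-fucosidase** removes the terminal deoxy-hexose (F→L, E→D), at most
  one per oligosaccharide in shift prediction.  **β-galactosidase**
  removes terminal hexoses from L and P (L→X, P→Y), up to two per
  oligosaccharide (XLLG has two removable galactoses); F is resistant
  because its galactose is capped by the fucose.  The enzyme sold as
  E-BGLAN is described with both α- and β-specificity labels in the
  literature; the model encodes only "removes the terminal hexose of L
  and P", which both readings imply.
* **Driselase** reduces an XGO to free monosaccharides except one
  isoprimeverose (Xyl-α-1,6-Glc) per substituted backbone unit —
  isoprimeverose release is the classic xyloglucan diagnostic.
* **Saponification** is an optional pre-step zeroing the acetyl count.

Mass conservation (Σ product masses = substrate + cuts × water) holds by
construction and is property-tested.  Acetyl groups travel with the
reducing-end product of an endo cut, an arbitrary but mass-neutral
choice forced by acetyl position being unresolvable.  Partial digestion
is a spectrum-level phenomenon (precursor and product co-present), not a
kinetic one.

`predict_shift_pairs` defaults to a single removal per peak (the way
shift lines are drawn when reading spectra by eye); multi-step
intermediates are available via `max_removals` and are always used by
the differential analysis.

## Spectrum analyses

Intensities are semi-quantitative: spectra are normalised to total ion
intensity and intensity is used only for presence/fold-change decisions.
"Disappeared" means absent or down ≥ 5-fold in relative intensity;
"partially degraded" means down ≥ 1.5-fold; both configurable.

Ladder detection labels every ordered peak pair whose Δm/z matches a
step (Hex 162.053, Pent 132.042, dHex 146.058, HexA 176.032, Ac 42.011,
plus the 294.095 xylosyl-glucose repeat) within tolerance; connected
components are the reported series.

Annotation ranks a peak's candidates by:

1. absolute mass error, with errors within 0.05 Da of a cluster's best
   treated as ties (the near-degeneracy scale above — sub-quantum
   differences are instrument noise, not evidence);
2. absence of *contradicting* enzyme evidence — a peak that survived an
   exo treatment argues against candidates whose every realisable
   structure carries that enzyme's target sidechain;
3. presence of *supporting* enzyme evidence — the peak vanished and the
   candidate contains the removed residue class, or the candidate plus
   the removed residues explains a vanished precursor;
4. grammar realisability (compositions with at least one structure
   first), then fewer distinct residue classes, then the display
   representative for a stable order.

Peaks matching a pure-Hex composition are flagged as members of the
contaminating hexose-oligomer ladder; the flag is computed from the
composition, never matched against a hard-coded list.

## Tandem MS

Only neutral losses from the sodiated parent are modelled (plus the two
cross-ring neutrals, 60.021 and 120.042 Da); B/C/A/X taxonomy adds
nothing for sodiated glycan parents.  Terminality follows glycosidic
topology via each code's `ms_terminals` table; notably P exposes *both*
its galactose and its galacturonic acid because they decorate the same
xylose — which is exactly why a P-containing pentasaccharide shows
terminal Pent, Hex and HexA simultaneously.  The reducing-end glucose is
removable only when unsubstituted; a non-reducing-end backbone unit
leaves as a composite loss of all its residues (a bare G unit is thus a
depth-1 terminal hexose; an X unit a depth-2 composite).  Because
branching order is not mass-determinable, inference reports residue-class
sets and unordered loss pairs, never sidechain positions.

## Synthetic data

The generator emulates: theoretical adduct peaks with Gaussian m/z
jitter *in Da* (mass-independent at this range and reporting scale, so
ppm jitter would add nothing but a parameter), lognormal intensity noise
of a given CV, a Hex₃..Hex_n contaminant ladder, and uniform-random
decoy peaks — uniform placement is adversarial for the enumerator, since
some decoys land within tolerance of real compositions.  Digestion
experiments move a `completeness` fraction of each susceptible
structure's abundance to its products (completeness < 1 reproduces
partial-degradation co-presence) and record full ground truth.

What it does **not** emulate: isotope envelopes, detector saturation,
baseline/peak-shape effects, matrix clusters, ion-suppression between
analytes.  Passing recovery tests therefore show the *logic* is sound
under calibrated noise, not that real spectra of arbitrary quality will
annotate as cleanly.

Default stochastic test conditions: 0.1 Da jitter, 10 decoys,
12-structure pool with one fucosidase companion, 50 seeds — under which
the generating composition is recovered in every candidate list and
top-ranked for ≥95% of true peaks.

## Numerical choices and degenerate inputs

* Rounding: "truncate" is floor; "nearest" is Python's round.
* Peaks closer than 1e-6 Da merge by intensity sum at construction.
* Empty compositions are rejected by mass functions; unachievable
  compositions yield empty structure lists (not errors); a
  single-peak spectrum yields an empty series graph.
* Spectra are immutable and sorted at construction; all randomness flows
  from one integer seed through `numpy.random.Generator`.

## Known limitations

* No linkage positions, anomeric configuration or 3-D structure — this
  is mass-level annotation only.
* Enzyme rules are idealised specificities; unusual activities
  (transglycosylation, relaxed subsite requirements) are not modelled.
* The dHex/HexA near-degeneracy is only resolvable with companion
  enzyme spectra (or higher mass accuracy than integer MALDI); without
  them the ranking falls back to parsimony.
* mzML ingestion is not built in; peak lists are delimited text.
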