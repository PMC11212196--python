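# Methods

## The model

`rxncure` treats a reaction dataset as its own error model: if most records
of a transformation class are correct, the transformation rule they share
can be recovered by consensus and then used to audit every record. The
package therefore never consults external rule sets; everything it applies
it first extracts.

A reaction is a pair of heavy-atom molecular graphs (hydrogens implicit,
folded into per-atom counts; hydrogen-only molecules such as H2 keep their
atoms but contribute nothing to center detection). Atom-map numbers pair
reactant and product atoms. The **condensed graph of reaction (CGR)** is
the superposition of the two sides: one node per atom, one edge per atom
pair bonded on either side, labelled `(order_before, order_after)` with
absent bonds as order 0, plus per-node hydrogen and charge deltas. The
reaction center is exactly the set of mapped atoms incident to a changed
edge or carrying a nonzero delta (or a cross-side element mismatch, which
flags a recorded-structure error).

Two CGRs are compared as labelled graphs up to isomorphism: node labels
are (element before, element after, Δh, Δcharge), edge labels the order
pair, and map numbers themselves are *not* compared. Reactant-side map
numbers that never occur on the product side are treated as unmapped. This
makes the comparison invariant under consistent renumbering (curation
assigns fresh map numbers to restored fragments) while still detecting
every transposition of two non-equivalent atoms, which is the property the
map-error metric needs.

## Generic templates

A generic template is a radius-0 retro transformation: product-side
pattern = the center atoms with their mutual bond orders; reactant-side
pattern = the same atoms plus complete leaving groups (connected components
of reactant atoms absent from the product, adjacent to a center atom).
All atom-level constraints except element are discarded, with three
exceptions:

* **radical reactions** — any center atom with unpaired electrons switches
  on explicit H counts for all center atoms (H transfer is otherwise
  invisible at radius 0);
* **charge transfer** — any center atom changing formal charge switches on
  explicit charges for center atoms;
* **disjoint centers in one product molecule** — bridged by an unweighted
  shortest path over mapped atoms (ring-opening chemistry needs the
  intervening atoms to reassemble the ring). When several shortest paths
  exist, one is chosen deterministically (smallest endpoint map pair, then
  smallest map sequence); which path the original protocol takes is
  unobservable, and any single shortest path satisfies the "no redundant
  atoms" guarantee.

Leaving-group atoms additionally keep nonzero formal charges — without
them charged leaving groups could not be rebuilt into valid molecules.

Templates are serialized in an atomic-number SMARTS dialect
(`[#6:1]-[#6:2]-[#8:3]>>Br-[#6:1].[#6:2]=[#8:3]`). Canonical form: maps
are renumbered 1…k in the RDKit canonical output order of the product
pattern, the string is written by a DFS following that canonical order
(leaving-group atoms first within a fragment, fragments sorted), so
isomorphic patterns always produce identical strings. A parallel
`reduce_detailed_template` entry point reduces an RDChiral-style detailed
retro template to the same generic form, by computing the template's own
mini-CGR to find its centers.

**Canonicalization.** Two templates whose product sides and reactant sides
are each graph-isomorphic (maps ignored) describe the same transformation
written through different atom correspondences. Mapping errors inflate the
bond-change count (counted over atom pairs with at least one mapped atom;
formation, breakage and order change each count 1; leaving-group-internal
bonds do not count), so the merged representative is the member with the
fewest changes — the principle of minimum chemical distance — with ties
broken by the lexicographically smallest canonical string. Duplicate
reactions (identical mapping-agnostic reaction keys) count once toward
frequency, so a duplicated bad record cannot buy its template past the
filter. Filtering happens after merging; the default threshold removes
templates seen ≤ 5 times and is configurable.

## Curation

Templates are tried in descending frequency (ties by canonical string).
Pattern embedding is subgraph *monomorphism* (extra bonds between matched
atoms are tolerated, as in SMARTS matching) with aromatic bonds a distinct
order. For each embedding the products are rewritten: matched-pair bonds
follow the reactant pattern, unmatched atoms and bonds copy through with
maps preserved, leaving-group atoms are attached fresh. Rewritten atoms
lose their chirality and get every valence-consistent hydrogen completion
(see table below); assignments that fail RDKit sanitization are discarded,
as are candidates whose rewrite overflows every allowed valence.

A candidate is accepted when the original reactant multiset is contained
in it, comparing canonical SMILES ignoring maps *and* stereo — template
output is necessarily stereo-free, and stereo is reinstated afterwards by
replacing each curated molecule that matches an original one with a copy
of that original carrying the curated map numbers (exact graph matching on
element/charge/H labels gives the atom correspondence). Among passing
candidates of the winning template the one adding the fewest heavy atoms
wins, then canonical order. Outcomes: `validated` (nothing changed),
`repaired` (fragments added and/or CGR changed), `removed` (no template
accepted the record). Curation is idempotent: re-curating a repaired
record validates it unchanged.

Valence table defaults (bond-order sums; configurable): B 3; C 4; N 3 /
N⁺ 4 / N⁻ 2; O 2 / O⁻ 1 / O⁺ 3; halogens 1 (anions 0); P 3 or 5;
S 2 or 6 (S⁻ 1); Si 4. Unknown element/charge pairs fail loudly rather
than guessing. Aromatic bonds contribute 1.5 and the sum is floored, which
is exact for ring atoms with two aromatic bonds and conservative for
fusion atoms.

Optional by-product balancing groups reactant atoms absent from the
products into fragments, caps each severed bond with that many hydrogens,
and appends neutral, sanitizable fragments to the product side; heavy
atoms then balance exactly. Fragments that cannot be neutralized by
hydrogen addition alone are skipped with a warning.

## Synthetic benchmark

The fixture generator emulates five single-step families — carbonyl
arylation (aryl halide + aldehyde), Williamson ether synthesis, reductive
amination, amide coupling, Diels-Alder — over substituent pools (5 alkyl ×
6 aryl, or 3⁵ ring-substitution patterns for the cycloaddition). Products
are built first and fully mapped; reactants are derived by a hand-coded
inverse edit per family with the correspondence tracked by construction,
so mappings are correct by construction and independent of the template
machinery under test. Leaving-group atoms are left unmapped, as a mapping
tool would leave them. Two family sets are predefined: unique leaving
groups (one template per family) and competing leaving groups (two per
family, mixed 65:35, so the majority template outranks the minority one).

Noise injection corrupts `floor(ratio·n)` records, chosen without
replacement, one error each, type drawn from a configurable distribution
(default uniform over three types):

* *missing reactant* — one reactant molecule deleted uniformly
  (single-reactant records fall back to another type);
* *structural modification* — one of four product edits (add C, add O at
  an H-bearing site; substitute a non-aromatic C by O or N where valence
  allows) at a uniformly chosen valid site;
* *map swap* — transposition of two same-element product map numbers,
  restricted to pairs whose swap actually changes the CGR (swapping
  topologically equivalent atoms is a no-op that would poison the labels;
  cross-element swaps are structure errors, not mapping errors, so they
  are excluded). Swaps are not restricted to center atoms.

Identical seeds give byte-identical datasets and reports. Scoring:
missing-reactant success = curated reactant multiset equals the pristine
one (map/stereo-agnostic); structural detection = record removed; map
curation = curated CGR equals the pristine CGR; residual proportion =
surviving fraction.

## Problem sizes and what the tests show

The shipped study conditions are 3 families × 200 reactions with 15%
noise, a scale at which extraction + curation completes in a few seconds
while every template clears the frequency threshold. Under these
conditions all three recovery rates reach 100% on the unique-leaving-group
set, and exact missing-reactant recovery falls to roughly 65–85% on the
competing-leaving-group set — the frequency-preference failure mode, where
a minority-leaving-group reactant is rebuilt with the majority leaving
group.

These fixtures are deliberately idealized: mappings are perfect outside
the injected errors, families are chemically disjoint, molecules are small
and stereo-sparse, and every clean record's template survives filtering.
Passing therefore demonstrates the correctness of the machinery (center
detection, canonicalization, rewrite, scoring), not the recovery rates to
expect on mined data, where template diversity, unbalanced records,
mapper noise and rare-but-valid chemistry lower both the residual
proportion and missing-reactant recovery substantially. The benchmark CLI
accepts any external atom-mapped reaction file for that purpose.

## Known limitations

* Multi-step records are not decomposed; they fail template matching and
  are removed.
* Rare but valid reactions below the frequency threshold are removed —
  an accepted cost of the consensus assumption.
* Atom mapping is never computed de novo; inputs must carry maps (an
  external mapper can be run upstream).
* Stereochemistry at rewritten centers cannot be inferred from a generic
  template (e.g. phosphorus chirality in a restored phosphite); only
  stereo present in the original record is reinstated.
* The same-bond-order monomorphism cannot match a template across
  tautomeric or resonance-delocalized renderings of the same motif.
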