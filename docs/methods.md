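# Methods

## Model and assumptions

terescore implements an equivalency-factor-style additive potency
score for mixtures of estrogen-mimicking compounds. Each compound *i*
in a formulation contributes, per receptor channel *r* ∈ {α, β},

    c_i^r = d_i · RBA_i^r / 100

where *d_i* is the daily intake in aglycone-equivalent milligrams and
RBA_i^r is the compound's relative binding affinity expressed as a
percentage of estradiol's binding. The Theoretical Efficacy is
TE = Σ_i (c_i^α + c_i^β) in the default *combined* mode, or Σ_i c_i^β
in *beta_only* mode; TERE renders TE against the estradiol reference
of 100 as the fraction 1/x with x = 100/TE, computed from the
**unrounded** TE (published worked examples occasionally divide by a
pre-rounded TE, which shifts the denominator in the second decimal;
the unrounded rule is the only self-consistent one).

Assumptions, stated bluntly:

- **Additivity.** Contributions sum linearly; no synergy, antagonism,
  dose–response saturation, EC50/Hill behaviour, or receptor
  cooperativity. The score is meaningless where such effects operate.
- **Affinity ≈ potency.** In-vitro competitive-binding RBA is used as
  a proxy for in-vivo estrogenic potency. Pharmacokinetics —
  entero-hepatic absorption, hydrolysis, sulfation/glucuronidation,
  equol conversion, bioavailability differences — are deliberately
  outside the model.
- **Channel semantics.** ER-alpha binding is bookkept as the risk
  channel, ER-beta as the benefit channel; the package reports the
  partition and the absolute alpha load but imposes no alpha-load
  cutoff (no defensible threshold exists in the underlying data).

## Two scoring modes

The tabulated worked examples sum both channels; the dose-threshold
argument for single-compound genistein (1/22.8 at 10 mg, 1/15.2 at
15 mg) reproduces only from the beta channel alone. Both conventions
are therefore first-class: `combined` (default) and `beta_only`,
selected per call or by CLI flag. In either mode the risk/benefit
partition is always computed over both channels, so switching mode
changes TE and TERE but not the partition or the alpha load.

## Relevance threshold

`classify_relevance` flags a TERE denominator strictly greater than
the threshold (default 15.2) as LOW. The anchor is the minimal
genistein dose observed to reduce hot flushes: 10 mg/day
(denominator 22.8 on the beta channel) showed no relevant
bioactivity, 15 mg/day (denominator 15.2, conventionally rounded to
"1/15") did. The boundary case is therefore classified
POTENTIALLY_RELEVANT: the threshold *is* the weakest formulation with
observed effect. The source narrative's phrasing ("equal or under
1/15 is too low") conflicts with its own 15 mg example; this package
follows the examples, which are the operative derivation. The
threshold is a single tunable parameter (`threshold_denominator`,
dimensionless denominator units) for users who read the evidence
differently.

## Affinity data

The packaged table (label `fokialakis-default`) stores the
competitive-binding RBAs, on the printed percentage scale:
estradiol 100/100, daidzein 0.031/0.020, genistein 0.860/43.9,
formononetin 0.084/0.017, biochanin A 0.094/0.010 (α/β). Estradiol's
beta entry is reported in the source as "≤100" and stored as exactly
100 so the reference score is well defined. Glycitein, never assayed,
resolves through a one-hop proxy onto daidzein — its gut metabolites
and typically small intake make daidzein the conventional stand-in.
Proxy chains are forbidden; dangling proxies and negative affinities
are rejected at construction. User-supplied tables (YAML or 3-column
CSV) may omit estradiol: the TERE reference of 100 is definitional,
not data. No guidance is offered for reconciling conflicting
published affinity sets; the user picks one table per run.

## Dose conversion

Conversion of conjugates to aglycone equivalents is mass-ratio based
(mg-to-mg): intake × m(parent)/m(conjugate), the field's
"aglycone equivalents" convention; molar (µmol) dosing is out of
scope. Molar masses are computed from Hill-notation molecular
formulas with 4-decimal standard atomic weights, never tabulated, so
the formula is the single source of truth. The default registry
carries the five aglycones, the three 7-O-glucosides, and the
6″-O-malonyl (+C3H2O3) and 6″-O-acetyl (+C2H2O) esters of each
glucoside. Every table-reported intake defaults to
`is_aglycone_equivalent = true`, because published trial doses are
conventionally already aglycone equivalents; conversion is opt-in per
component.

## Numerical choices

- TERE denominators come from the unrounded TE; acceptance-style
  comparisons against published values use ±1 % relative, because the
  published tables round intermediates inconsistently.
- Component intakes resolving to the same compound are merged with
  `math.fsum` and totals are accumulated in sorted-name order, so
  reordering or splitting components leaves every output bit-identical.
- A formulation whose affinities are all zero scores TE = 0 with an
  explicit infinite denominator, a LOW flag, and an undefined (None)
  risk/benefit partition; `risk_benefit` raises only when asked for
  the undefined partition explicitly.
- Report rendering: contributions and TE at 6 significant digits,
  alpha load at 3, percentages at 1 decimal, TERE as "1/x" with x to
  2 decimals. Compound names are canonicalized to lowercase with
  hyphens treated as spaces ("biochanin A" ≡ "biochanin-a").
- Decimal parsing accepts period separators only; locale-dependent
  input is rejected for reproducibility.

## Built-in worked examples

The fixture module regenerates, deterministically and from code, the
demonstration inputs: the two complementary 100 mg mixes, a soy OTC
preparation (12/1.26/45 mg daidzein/glycitein/genistein), a
red-clover extract (0.1/16/1/26 mg daidzein/formononetin/genistein/
biochanin A), a soy-germ dose (1206 mg pooled daidzein-equivalent +
185 mg genistein — pooling daidzein with glycitein is lossless under
the proxy rule), a nine-trial comparison set, and the 10/15 mg
genistein threshold cases. The red-clover example's published totals
are internally inconsistent (the printed alpha total is not the sum
of its own printed cells), so tests assert only model invariants for
it, never its printed TE/TERE. One trial in the comparison set
(48/24/8 mg genistein/daidzein/glycitein) has a printed alpha load
(0.43) that does not follow from the affinity table (it computes to
0.42272); its TERE does reproduce and is asserted, the load is
asserted at its affinity-derived value.

These fixtures are synthetic encodings of published trial
compositions, not measured data: passing tests show the arithmetic
reproduces the published worked examples, not that the score predicts
clinical outcomes. Outcome annotations ("24% reduction in hot
flushes", …) are carried as opaque strings for the comparison report
and never interpreted.

## Problem sizes

Everything is desk-scale: formulations of 1–6 compounds, an affinity
table of five records, sixteen fixture formulations. The full test
suite and the acceptance script each run in a few seconds.

## Known limitations

- No binding-affinity prediction, docking or QSAR; affinities are
  always supplied data.
- No pharmacokinetic modelling; two formulations with equal TERE can
  differ greatly in vivo.
- No statistical association between TERE and the annotated clinical
  outcomes is computed — the comparison report juxtaposes them only.
- The relevance threshold rests on a two-point dose comparison for a
  single compound and should be treated as indicative.
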