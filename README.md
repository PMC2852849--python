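# terescore

Receptor-affinity-weighted potency scoring for mixtures of
estrogen-mimicking compounds — isoflavones and other phytoestrogens —
aimed at anyone who needs to compare formulations used in different
clinical trials or sold as OTC supplements when the compound
compositions differ.

## The model

Isoflavones (genistein, daidzein, glycitein, formononetin, biochanin A)
bind the two estrogen-receptor subtypes with very different relative
binding affinities (RBA, percent of estradiol's binding; estradiol =
100). ER-beta binding is the benefit channel (bone, cardiovascular,
CNS); ER-alpha binding is the risk channel (tumour-proliferation
concern). For a formulation with daily intakes *d<sub>i</sub>* (mg/day,
aglycone equivalents) the per-receptor bound contribution of compound
*i* is

```
c_i^r = d_i · RBA_i^r / 100        r ∈ {α, β}
```

and the **Theoretical Efficacy** is the additive total

```
TE = Σ c_i^α + Σ c_i^β             (combined mode; beta_only sums only c^β)
```

**TERE** (Theoretical Efficacy Related to Estradiol) expresses TE
against the estradiol reference of 100 as the fraction 1/x with
x = 100/TE. The package also reports the risk/benefit partition
(100·Σc^α/TE vs 100·Σc^β/TE in combined mode), the absolute alpha
load Σc^α, and a relevance flag: formulations with a TERE denominator
above ≈15 (the minimal genistein dose observed to reduce hot flushes)
are classified as unlikely to show clinically relevant bioactivity.
The model is purely additive — it does not apply where compounds act
synergistically or antagonistically.

Conjugated forms (genistin, daidzin, glycitin and their
malonyl/acetyl esters) are converted to aglycone-equivalent
milligrams by the molar-mass ratio parent/conjugate before scoring.

## Worked example

```
$ tere fixtures fx              # write the built-in worked-example files
$ tere score fx/demo_assays.csv
# affinity set: fokialakis-default   mode: combined
label    annotation  components                        TE       TERE    alpha_load  risk_percent  relevance
-------  ----------  --------------------------------  -------  ------  ----------  ------------  --------------------
assay-1              25 mg daidzein + 75 mg genistein  33.5828  1/2.98  0.653       1.9%          POTENTIALLY_RELEVANT
assay-2              75 mg daidzein + 25 mg genistein  11.2283  1/8.91  0.238       2.1%          POTENTIALLY_RELEVANT
```

Two trials that both use "100 mg of isoflavones" differ three-fold in
theoretical potency once affinities are weighted in: the
genistein-rich mix reaches about a third of estradiol's reference
activity (TERE 1/2.98), the daidzein-rich mix only a ninth. Both put
≈2 % of the bound total on the alpha (risk) channel, but the absolute
alpha loads differ (0.653 vs 0.238).

The same from Python:

```python
from terescore import Formulation, FormulationComponent, score_formulation

mix = Formulation("assay-1", (
    FormulationComponent("daidzein", 25),
    FormulationComponent("genistein", 75),
))
bd = score_formulation(mix)
print(bd.te, bd.tere_fraction, bd.risk_percent)
# 33.58275 1/2.98 1.9437062182221532
```

`tere compare fx/trial_comparison.csv` ranks a nine-trial comparison
set by TE; `tere convert` rewrites conjugate intakes as aglycone
equivalents; `tere affinity export` prints the packaged affinity
table, and `--affinity` accepts an alternative table (YAML or CSV) for
any published affinity set.

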