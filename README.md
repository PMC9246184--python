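# kincal — pedigree-constrained Bayesian calibration of radiocarbon dates

Ancient-DNA kinship analysis reconstructs pedigrees of buried individuals, and
a pedigree fixes the order in which its generations died.  `kincal` exploits
that relative chronology when calibrating the individuals' radiocarbon dates:
instead of calibrating each date on its own, the dates are modelled jointly
under the constraint that generation 1 died before generation 2, and so on.
On flat or wiggly stretches of the calibration curve this can shrink 2-sigma
calendar ranges by half or more and resolve apparent inversions of the death
order.  The intended users are archaeologists and archaeogeneticists working
with radiocarbon-dated family groups.

## Model

A determination `x ± σ` (conventional ¹⁴C years BP) calibrates against a
curve `μ(θ), σ_c(θ)` to a posterior over calendar years `θ`:

    p(θ | x) ∝ exp( −(x − μ(θ))² / 2(σ² + σ_c(θ)²) )

For a pedigree, the generations form an ordered sequence of phases delimited
by boundaries `b_0 ≤ b_1 ≤ … ≤ b_K`; each death year `θ_i` of phase `j`
lies in `[b_{j−1}, b_j]`.  The joint posterior is

    p(θ, b | x) ∝ Π_i L_i(θ_i) · Π_j (b_j − b_{j−1})^(−n_j)
                  · Π_{j ∈ intervals} N(b_j − b_{j−1}; T_j, s_j)

with the uniform-phase span prior `(span)^(−n_j)` and optional normal
interval priors expressing known generation gaps (e.g. a 20-year reproductive
age).  The posterior is sampled by Metropolis-within-Gibbs; per-date
agreement indices `A_i = 100·Σ p′p / Σ p²` quantify how well each modelled
marginal agrees with its unconstrained calibration (values below ~60 flag a
data–model conflict), and the model agreement combines them as
`100·Π(A_i/100)^(1/√n)`.

Supporting tools cover the human bone collagen offset (HBCO, a 0–25 year lag
subtracted from the conventional age), the collagen C:N quality gate
(2.9–3.6), post-hoc year-of-death separation caps (deaths of consecutive
generations at most `sep` years apart), span sweeps across a curve, and a
simulation framework that places a five-generation pedigree on plateau,
steep, mixed and anchor-point curve regimes.

## Calibration curves

Any IntCal-format `.14c` file can be loaded with `kincal.load_curve(path)`
(calendar storage is a signed year, `calAD = 1950 − calBP`).  The package
does not redistribute the IntCal datasets; it bundles a fully *synthetic*
study curve (`kincal.study_curve()`) that emulates the structural regimes of
an atmospheric curve — a Hallstatt-type plateau with two sub-plateaus split
at 540 cal BC and internal troughs, a steep stretch at 7600–7500 cal BC, a
mixed wiggle section around 2000 cal BC — so the modelling machinery and the
simulations are fully reproducible offline.  Place public IntCal files under
`src/kincal/data/curves/` (e.g. `intcal13.14c`) to work with measured data;
the test suite then also exercises its checks against published worked
examples.

## Worked example

```python
import kincal as kc

curve = kc.study_curve()
ped = kc.make_pedigree(kc.scenario("plateau"))          # A1 dies 655 cal BC, in a plateau trough
dates = kc.simulate_dataset(ped, curve, err=25)         # ages = curve values, ±25 BP
spec = kc.ModelSpec(phases=tuple(
    tuple(i.id for i in ped.individuals if i.generation_level == k + 1)
    for k in range(5)
))
summary = kc.run_model(spec, dates, curve, kc.SamplerSettings(seed=42))
print(f"model agreement: {summary.model_agreement:.0f}")
for did in ("A1", "B1", "E1"):
    unmod, mod = summary.unmodelled_ranges2[did], summary.ranges2[did]
    true = ped.by_id(did).yod
    print(f"{did}: true YoD {kc.format_year(true)}, "
          f"unmodelled {kc.format_year(unmod.oldest)} - {kc.format_year(unmod.youngest)} "
          f"({unmod.outer_span:.0f} yr) -> modelled {mod.outer_span:.0f} yr, "
          f"covered: {mod.contains(true)}")
```

prints

    model agreement: 128
    A1: true YoD 655 cal BC, unmodelled 755 cal BC - 435 cal BC (320 yr) -> modelled 120 yr, covered: True
    B1: true YoD 644 cal BC, unmodelled 760 cal BC - 445 cal BC (315 yr) -> modelled 130 yr, covered: True
    E1: true YoD 560 cal BC, unmodelled 770 cal BC - 480 cal BC (290 yr) -> modelled 175 yr, covered: True

A1's death falls in a down-wiggle of the plateau, so its single-date range
spans 320 years and makes it look like the *youngest* family member; the
sequenced model cuts that to 120 years, restores the true generation order,
and still covers every true death year.  The high model agreement says the
order constraints sit comfortably with the radiocarbon evidence.

The same machinery drives the command line:

    kincal calibrate                          # bundled case-study table, per-date ranges
    kincal model --pedigree obkr --seed 11    # sequenced model + OxCal-dialect export
    kincal simulate --scenario anchor --seed 7
    kincal sweep --bp-start 6600 --bp-end 2021

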