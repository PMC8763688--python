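"""Virtual-population uncertainty for the 30-day dermal scenario and the
margin of internal exposure (MoIE).

Individuals sample age 16–70 and body weight 45–100 kg (isometric organ
scaling); parameter uncertainty draws Fu from its stated normal
distribution. Every individual runs the bi-daily 30-day dermal regimen at
the most conservative penetrated fraction (5.3%); the day-30 C_max/AUC
distribution is summarized as mean and CI(5–95)%.
"""

import homopbk as h

substance = h.packaged_substance()
population = h.generate_population(
    h.PopulationSpec(species="human", n_individuals=10, seed=1))
draws = h.sample_uncertain_parameters(
    {"fraction_unbound": h.UncertainParameter(0.014, 0.0014, 1e-4, 1.0)},
    len(population), seed=2)


def build(individual, d):
    sub = substance.replace(fraction_unbound=float(d["fraction_unbound"]))
    return h.human_dermal_model(fraction=0.053, applied_dose=103.0,
                                area=17500.0, substance=sub,
                                individual=individual)


regimen = h.DoseRegimen(route="dermal", dose=103.0, n_days=30,
                        doses_per_day=2, application_area=17500.0,
                        product_fraction=0.10)
result = h.population_simulate(build, regimen, population,
                               parameter_draws=draws, t_end=720.0,
                               window=(696.0, 720.0), seed=1)

for endpoint in ("cmax", "auc_0_24"):
    s = result.summary[endpoint]
    unit = "ng/mL" if endpoint == "cmax" else "ng·h/mL"
    print(f"day-30 {endpoint:>8}: mean {s['mean']:8.1f} {unit}, "
          f"CI(5-95)% [{s['ci5']:.1f}, {s['ci95']:.1f}]")

# MoIE: internal exposure at the oral point of departure vs consumer use.
# Run the oral model at a PoD-like dose and compare last-day AUCs.
oral = h.rat_reference_model(with_oral=True)
spec = h.calibrate_oral_absorption(oral, h.DoseRegimen(route="oral",
                                                       dose=60.0), 0.5)
oral = h.rat_reference_model(with_oral=True, oral_spec=spec)
res = h.simulate(oral, h.DoseRegimen(route="oral", dose=60.0, n_days=7),
                 t_end=168.0)
pod_auc = h.compute_metrics(res, window=(144.0, 168.0)).auc_0_24
human_auc = result.summary["auc_0_24"]["mean"]
moie = h.compute_moie(pod_auc, human_auc)
print(f"\nMoIE = PoD AUC / human AUC = {pod_auc:.0f}/{human_auc:.0f} "
      f"= {moie.ratio:.1f} -> {'PASS' if moie.passes else 'FAIL'} "
      f"vs safety factor {moie.threshold:.0f}")
print("(the verdict depends on the whole-body parameterization: this "
      "implementation predicts higher dermal plasma levels than the "
      "platform the study used — see docs/methods.md, Limitations)")
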