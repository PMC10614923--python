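"""Call positive vs negative intonation against shuffle nulls.

Simulates breath-modulation (model 1) and laryngeal-constriction (model 2)
syllables, correlates each USV's pitch contour with its expiratory airflow,
builds shuffle nulls (pitch paired with other USVs' airflow and vice versa),
and calls each USV positive, negative, or indeterminate.
"""
import numpy as np

import intonate as it

cfg = it.SimConfig()


def to_events(ds, base=0):
    events, airs = [], []
    for k, (trace, contour, rec) in enumerate(ds):
        events.append(it.UsvEvent(
            id=base + k, onset=rec["syllables"][0]["onset"],
            offset=rec["syllables"][-1]["offset"],
            syllables=[(s["onset"], s["offset"]) for s in rec["syllables"]],
            type_label=rec["type"], contour=contour))
        airs.append(trace)
    return events, airs


ev1, a1 = to_events(it.simulate_usv_dataset(60, ["complex", "down fm"],
                                            "model1", cfg, seed=10))
ev2, a2 = to_events(it.simulate_usv_dataset(60, ["up fm"], "model2", cfg,
                                            seed=11), base=len(ev1))
results, summary, nulls = it.intonation_analysis(ev1 + ev2, a1 + a2,
                                                 n_perm=200, seed=12)

print(summary[["type_label", "n", "median_r", "n_positive", "n_negative",
               "n_indeterminate"]].to_string(index=False))
rs = np.array([r.r for r in results], dtype=float)
print(f"\nbreath-modulation USVs:       median r = {np.median(rs[:len(ev1)]):+.3f}"
      "  (pitch follows measured flow)")
print(f"laryngeal-constriction USVs:  median r = {np.median(rs[len(ev1):]):+.3f}"
      "  (narrowing raises pitch while impeding flow)")
null = nulls[None]
print(f"pooled null: {null.r_values.size} shuffled correlations, "
      f"2.5/97.5% quantiles {np.quantile(null.r_values, .025):+.2f} / "
      f"{np.quantile(null.r_values, .975):+.2f}")
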