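"""Classify promoter codes and compute the applicability domain.

Five independent optimization runs from randomized starts give five
weight vectors; a code whose weight moves the endpoint the same way in
every run is a promoter of increase or decrease.  The applicability
domain flags records whose codes are distributed too differently
between the active-training and calibration sets.
"""

import quasicw as q

records = q.load_thp1_records()
split = q.load_split1()

traces = q.multi_run(records, split, q.OptimizationConfig(seed=0, n_runs=5))
cls = q.classify_promoters(traces)
print("promoters of viability decrease:", cls.codes_in("decrease"))
print("promoters of viability increase:", cls.codes_in("increase"))
# [Mn] and [Co] recur as decrease promoters: manganese and cobalt
# oxides are the consistently cytotoxic ones in this panel.

active = [r for r in records if r.set_label == "A"]
calib = [r for r in records if r.set_label == "C"]
stats = q.code_frequency_stats(active, calib)
defects = {r.id: q.statistical_defect(r, stats) for r in records}
training = [r.id for r in records if r.set_label in ("A", "P")]
report = q.domain_report(records, defects, training)
print(f"defect threshold: {report.threshold:.4f}")
for lab, frac in sorted(report.outlier_fraction.items()):
    print(f"set {lab}: {frac:.0%} out of domain")
# Out-of-domain predictions are not trusted; the fraction estimates how
# much of each set the model can responsibly speak for.
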