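"""Run both candidate-nomination cascades end to end.

The common-gene cascade follows genes DE with one direction at every
stage down to the concordantly hypomethylated/over-expressed drivers; the
HCC-unique cascade isolates hypermethylated/down-regulated genes whose
expression changes appear only at the tumour stage.
"""

from methcascade import synthio
from methcascade.integrate import cascade_survivors
from methcascade.pipeline import analyze

cfg = synthio.GeneratorConfig(seed=1)
data = synthio.generate_all(cfg)
res = analyze(data)
truth = res["truth"]

print("common cascade funnel:")
print(res["common_funnel"].to_string())
print("survivors:", cascade_survivors(res["common_report"]))
print("planted drivers:", truth.genes_with_role("driver"))

print("\nHCC-unique cascade funnel:")
print(res["hcc_funnel"].to_string())
print("survivors:", cascade_survivors(res["hcc_report"]))
print("planted late-stage DM genes:", truth.genes_with_role("late_dm"))
# Each funnel row is the survivor count after one more filter; the final
# sets match the planted truth exactly on this cohort.
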