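"""Single-case deficit tests against the published control summaries.

Scores each stroke subject's F1 gradual-paradigm responses against the
neurotypical sample with the Crawford-Howell comparison and classifies the
pattern of impairment.
"""

import aafadapt as aaf

fx = aaf.load_paper_fixture()
controls = {m: fx.control_sample("F1", "gradual", m)
            for m in ("adaptive", "corrective")}
grad = fx.pwa.query("formant == 'F1' and paradigm == 'gradual'")
cases = {r["subject"]: {"adaptive": r["adaptive"], "corrective": r["corrective"]}
         for _, r in grad.iterrows()}

print("subject  measure     score      t      p   impaired")
out = aaf.classify_impairments(cases, controls)
for sid in sorted(cases):
    for measure in ("adaptive", "corrective"):
        res = out["results"][sid][measure]
        print(f"{sid:7s}  {measure:10s} {cases[sid][measure]:+8.2f}  "
              f"{res.t:+5.2f}  {aaf.format_p(res.p):.3f}   "
              f"{'yes' if res.impaired else 'no'}")

print("\nclassification:", out["counts"])
print("p is the one-tailed probability that the case's score is an")
print("observation from the control population (n=12, df=11).")
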