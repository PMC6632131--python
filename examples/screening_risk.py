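"""Post-test ESCC risk in a screening population.

Applies Bayes' rule to the published validation sensitivity (0.96) and
specificity (0.98) at real-world prevalences (31 per 100 000 for
Japanese men, 5.6 per 100 000 for women) to show how a blood test
reshapes individual risk: PPV is the risk after a positive result,
1 - NPV the residual risk after a negative one.
"""

from ecindex import ScreeningInputs, screening_metrics
from ecindex.ec_index import format_percent

for label, prevalence in [("Japanese men", 0.00031), ("Japanese women", 0.000056)]:
    m = screening_metrics(ScreeningInputs(prevalence, sensitivity=0.96,
                                          specificity=0.98))
    print(f"{label}: baseline risk {format_percent(prevalence)}")
    print(f"  after a positive test: {format_percent(m.ppv)}  (PPV)")
    print(f"  after a negative test: {format_percent(m.one_minus_npv)}  (1 - NPV)")
print("Low prevalence keeps the PPV small even for an accurate test; the "
      "near-zero 1 - NPV is what makes a negative result reassuring.")
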