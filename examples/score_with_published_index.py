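"""Score serum miRNA profiles with the published 6-miRNA EC index.

Builds two normalized log2 expression profiles — one resembling an ESCC
case (high miR-8073/miR-3196/miR-744-5p, low miR-6794-5p/miR-6820-5p/
miR-6799-5p) and one with the pattern reversed — and scores both with
the frozen published discriminant. A score above 0 is a positive
(cancer-suspect) call.
"""

from ecindex import PUBLISHED_EC_INDEX, ec_score

case_like = {
    "miR-8073": 9.5, "miR-3196": 10.2, "miR-744-5p": 8.8,
    "miR-6794-5p": 6.1, "miR-6820-5p": 5.9, "miR-6799-5p": 6.4,
}
control_like = {
    "miR-8073": 6.2, "miR-3196": 7.9, "miR-744-5p": 7.6,
    "miR-6794-5p": 8.8, "miR-6820-5p": 8.4, "miR-6799-5p": 8.1,
}

print("EC index =",
      " + ".join(f"({w})*{m}" for w, m in
                 zip(PUBLISHED_EC_INDEX.coefficients, PUBLISHED_EC_INDEX.mirna_ids)),
      f"+ ({PUBLISHED_EC_INDEX.intercept})")
for label, profile in [("case-like", case_like), ("control-like", control_like)]:
    score, call = ec_score(profile)
    print(f"{label:13s} score = {score:+.3f}  ->  {call}")
print("A score above 0 flags the profile as ESCC-suspect; at or below 0 "
      "it is called negative.")
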