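"""Generate a small synthetic cohort and print the summary tables.

The default recipe draws preoperative volumes log-uniform (median ~30 ml),
~91% clinically local cases, ~26% multifocal transformations, and
molecular/treatment labels at realistic frequencies. The analysis then
reports, per subgroup, how often the transformation was local (clinical
2-cm rule) and within the preoperative volume (overlay model).
"""

from lggspat import analyze_cohort
from lggspat.synthetic import generate_cohort

cases, truths, _ = generate_cohort(n=24, seed=11)
result = analyze_cohort(cases)

print(f"cohort: {len(cases)} cases "
      f"({sum(c.has_preoperative for c in cases)} with preoperative MRI)\n")

print("category counts (numerator/denominator, %):")
for row in result.summary.counts:
    print(f"  {row['metric']:<22} {row['numerator']}/{row['denominator']}"
          f" ({row['percent']})")

print("\nvolumes, median (Q1-Q3) in ml:")
for row in result.summary.descriptive:
    if row["n"]:
        print(f"  {row['metric']:<40} {row['median']:.1f}"
              f" ({row['q1']:.1f}-{row['q3']:.1f})  n={row['n']}")

print("\nsubgroup patterns  [clinical local | overlay within]:")
for row in result.summary.subgroup_patterns:
    print(f"  {row['subgroup']:<20} {row['clinical_local']:<14} {row['overlay_within']}")

# Most transformations are local and inside the preoperative tumor volume
# across every subgroup — the spatial signature this pipeline quantifies.
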