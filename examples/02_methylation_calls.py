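"""Three-state methylation calls under the two-replicate and pooled rules.

A CHG cytosine is called methylated when each replicate has at least five
reads and at least one methylated read (two-replicate rule), or when the
pooled replicates do (pooled rule, used for parental-allele methylomes).
"""

from endoepi.methylome import call_site_pooled, call_site_two_replicates

cases = [
    ((1, 5), (1, 7)),   # methylated in both replicates
    ((4, 4), (10, 20)), # replicate 1 below the 5-read floor
    ((0, 10), (0, 12)), # well covered, never methylated
    ((3, 10), (0, 12)), # methylated reads in only one replicate
]
print("rep1 (m/t)  rep2 (m/t)  two-replicate call   pooled call")
for rep1, rep2 in cases:
    two = call_site_two_replicates(rep1, rep2).status
    pooled = call_site_pooled([rep1, rep2]).status
    print(f"{rep1!s:11} {rep2!s:11} {two:20} {pooled}")

print("\nNote the third and fourth rows: evidence in a single replicate is not")
print("enough for the two-replicate rule, while pooling can rescue the call.")
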