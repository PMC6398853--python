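"""The Chinese Restaurant Process prior: rich-gets-richer seating.

With occupied tables of sizes 5, 2 and 1 and concentration alpha = 2, the
next arrival joins each table with probability proportional to its size and
founds a new table with probability proportional to alpha.
"""

from crpclust import prior_seating_probs

sizes = [5, 2, 1]
alpha = 2.0
probs = prior_seating_probs(sizes, alpha)

for size, p in zip(sizes, probs):
    print(f"join the table of {size}: {100 * p:.0f}%")
print(f"found a new table:   {100 * probs[-1]:.0f}%")
# Larger tables attract proportionally more arrivals, producing the
# exponentially decaying cluster-size profile typical of CRP clusterings.
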