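"""Comparing partitions: transfer distance and the two similarities.

P1 = {{1,2},{3,4}} and P2 = {{1},{2,3,4}} differ only in where participant 2
sits, so a single move reconciles them: transfer distance 1.
"""

from crpclust import (
    Partition,
    mirkin_similarity,
    transfer_distance,
    transfer_similarity,
)

p1 = Partition.from_blocks([[0, 1], [2, 3]])
p2 = Partition.from_blocks([[0], [1, 2, 3]])

td = transfer_distance(p1, p2)
print(f"transfer distance   TD = {td}")          # 1 move (participant 2)
print(f"transfer similarity TS = {transfer_similarity(p1, p2):.4f}")  # 1 - 1/3
print(f"mirkin similarity   MS = {mirkin_similarity(p1, p2):.4f}")    # 1 - 6/16
# TS rescales the move count by the worst case (N - 1); MS rescales the
# number of discordant item pairs by N^2. Both are 1 for identical
# partitions (up to relabeling) and live in [0, 1].
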