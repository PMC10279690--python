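"""Brute-force Benjamini-Hochberg step-up adjusted p-values.

Direct transcription of the step-up definition:
    p_adj(i) = min_{j >= i in sorted order} ( m * p_(j) / j ), capped at 1,
independent of any multiple-testing library.
"""


def bh_adjust(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj_sorted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * pvals[i] / rank)
        adj_sorted[rank - 1] = running_min
    adj = [0.0] * m
    for rank, i in enumerate(order, start=1):
        adj[i] = min(1.0, adj_sorted[rank - 1])
    return adj
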