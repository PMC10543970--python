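"""Shared independent oracles used by multiple test modules."""

import statistics


def reference_filter(x, k):
    """Brute-force median-then-moving-average filter with symmetric
    shrink-to-available edge windows; deliberately naive."""

    def one_pass(sig, agg):
        out = []
        half = k // 2
        for i in range(len(sig)):
            h = min(half, i, len(sig) - 1 - i)
            out.append(agg(sig[i - h : i + h + 1]))
        return out

    return one_pass(one_pass(list(x), statistics.median), statistics.fmean)
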