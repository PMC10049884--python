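"""Asymmetric coverage between linear measurement protocols.

Whether one protocol's measurements are "the same" as another's is expert
judgement, supplied as an explicit synonym table. Coverage of protocol B by
protocol A is the percentage of B's measurements that A also captures; the
matrix is genuinely asymmetric because protocols differ in size and synonym
pairs may be many-to-one.
"""

import morphodisc as md


def proto(prefix, size):
    return md.MeasurementProtocol(
        prefix,
        [md.Measurement(f"{prefix}_{i:02d}", 2 * i, 2 * i + 1) for i in range(size)],
    )


small = proto("small", 13)
large = proto("large", 22)
# expert judgement: the first six measurements correspond, and one "small"
# measurement subsumes two "large" ones
synonyms = [(f"small_{i:02d}", f"large_{i:02d}") for i in range(6)]
synonyms.append(("small_05", "large_06"))

print(f"small covers large: {md.protocol_overlap(small, large, synonyms):.2f}% "
      f"({7}/{len(large)} measurements)")
print(f"large covers small: {md.protocol_overlap(large, small, synonyms):.2f}% "
      f"({6}/{len(small)} measurements)")
print("the two directions differ: coverage is relative to the column protocol.")
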