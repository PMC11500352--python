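"""Independent brute-force reference for the window statistics and q values.

Deliberately written with plain Python loops and dicts over a flat
site-record representation so it shares no code path with the package.
Site records: ``(chrom, pos, ref_base, {sample: (nA, nC, nG, nT)})``.
"""

from statistics import median

BASES = "ACGT"
ALL_CLASSES = [x + y for x in BASES for y in BASES if x != y]


def oracle_windows(regions, window_size):
    """[(chrom, start, end)] tiles of the given regions."""
    out = []
    for chrom, rstart, rend in regions:
        start = rstart
        while start < rend:
            out.append((chrom, start, min(start + window_size, rend)))
            start += window_size
    return out


def oracle_delta_sets(
    sites,
    samples1,
    samples2,
    regions,
    window_size,
    min_coverage,
    snp_enabled=False,
    snp_threshold=0.80,
    min_sites_per_window=1,
):
    """Per-class window statistics computed by direct evaluation.

    Returns {class: {window_id: (n_sites, {sample: e}, z1, z2, delta)}}.
    """
    samples = list(samples1) + list(samples2)
    windows = oracle_windows(regions, window_size)
    result = {}
    for cls in ALL_CLASSES:
        x, y = cls[0], cls[1]
        yi = BASES.index(y)
        per_window = {}
        for chrom, wstart, wend in windows:
            e = {s: 0.0 for s in samples}
            n_sites = 0
            for schrom, pos, ref, quads in sites:
                if schrom != chrom or not wstart <= pos < wend or ref != x:
                    continue
                cov = {s: sum(quads.get(s, (0, 0, 0, 0))) for s in samples}
                if any(cov[s] < min_coverage for s in samples):
                    continue
                if snp_enabled:
                    snp = False
                    for s in samples:
                        if cov[s] >= min_coverage and cov[s] > 0:
                            if quads.get(s, (0, 0, 0, 0))[yi] / cov[s] >= snp_threshold:
                                snp = True
                    if snp:
                        continue
                n_sites += 1
                for s in samples:
                    e[s] = e[s] + quads.get(s, (0, 0, 0, 0))[yi] / cov[s]
            if n_sites >= min_sites_per_window:
                z1 = sum(e[s] for s in samples1) / len(samples1)
                z2 = sum(e[s] for s in samples2) / len(samples2)
                wid = f"{chrom}:{wstart}-{wend}"
                per_window[wid] = (n_sites, e, z1, z2, z2 - z1)
        result[cls] = per_window
    return result


def oracle_tail_count(values, threshold):
    if threshold < 0:
        return len([v for v in values if v <= threshold])
    if threshold > 0:
        return len([v for v in values if v >= threshold])
    return len(values)


def oracle_qvalues(delta_sets, focal_class, normalize=False):
    """q estimation: per-decoy tail ratio, median, tail-wise running minimum.

    ``delta_sets``: {class: {window_id: delta}}. Returns
    {window_id: (q_raw, q_final)}.
    """
    focal = delta_sets[focal_class]
    focal_values = list(focal.values())
    decoys = {
        c: list(d.values())
        for c, d in delta_sets.items()
        if c != focal_class and len(d) > 0
    }
    q_raw = {}
    for wid, d0 in focal.items():
        if d0 == 0:
            q_raw[wid] = 1.0
            continue
        estimates = []
        for decoy_values in decoys.values():
            num = oracle_tail_count(decoy_values, d0)
            if normalize:
                num = num * len(focal_values) / len(decoy_values)
            den = oracle_tail_count(focal_values, d0)
            estimates.append(min(1.0, num / den))
        q_raw[wid] = median(estimates)
    q_final = {}
    for wid, d0 in focal.items():
        if d0 == 0:
            q_final[wid] = min(1.0, q_raw[wid])
            continue
        candidates = [
            min(1.0, q_raw[other])
            for other, d in focal.items()
            if (d > 0) == (d0 > 0) and d != 0 and abs(d) <= abs(d0)
        ]
        q_final[wid] = min(candidates)
    return {wid: (q_raw[wid], q_final[wid]) for wid in focal}
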