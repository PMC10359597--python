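"""Event-driven lattice kernel for the scanning/reinitiation simulation.

The kernel is a continuous-time Monte Carlo of small ribosomal subunits
scanning a 1-nt lattice with hard-core exclusion (an open-boundary TASEP
with internal states).  It is compiled with numba; everything above it in
:mod:`gcn4set.scanning_model` is plain Python.

Scanner states
    0  43S scanning cap -> uORF1 (carries ternary complex)
    1  translating/terminating at uORF1 (dwell)
    2  40S scanning TC-less (post-uORF1)
    3  40S-TC scanning (reacquired ternary complex)
    4  translating/terminating at uORF4 (dwell)

Terminal fates (indices into the counts array)
    0  released after uORF1 termination      (prob 1 - eta)
    1  reinitiated at uORF4
    2  initiated at the GCN4 start codon
    3  ran past the GCN4 start TC-less (runoff)

Ternary-complex acquisition is a per-nucleotide Bernoulli event with
probability 1 - exp(-lambda/v) applied on each completed hop, so that the
probability of acquiring TC across a stretch of d nt is exactly
1 - exp(-(lambda/v) d) -- the distance-exponential form of the scanning
model -- independent of waiting times imposed by exclusion.  Dwell times
are exponential with mean ``uorf_dwell``.
"""

import numpy as np
from numba import njit

# status codes returned by the kernel
STATUS_OK = 0
STATUS_TIME_EXCEEDED = 1
STATUS_OVERFLOW = 2

_CAPACITY = 256  # max concurrent scanners; physical occupancy is O(1-10)


@njit(cache=True)
def run_tasep(alpha, v, p_bind, eta, uorf1_start, uorf1_stop, uorf4_start,
              gcn4_start, footprint, dwell_rate, max_time, n_replicates,
              seed):  # pragma: no cover - exercised via simulate_tasep
    np.random.seed(seed)
    pos = np.zeros(_CAPACITY, np.int64)
    st = np.zeros(_CAPACITY, np.int64)
    entry_t = np.zeros(_CAPACITY, np.float64)
    n = 0                      # active scanners; index 0 is frontmost
    t = 0.0
    counts = np.zeros(4, np.int64)
    occ_int = 0.0              # integral of occupancy dt
    occ2_int = 0.0             # integral of occupancy^2 dt
    resid_sum = 0.0            # summed residence times of completed scanners
    completed = 0
    entered = 0
    status = STATUS_OK

    while completed < n_replicates:
        total = alpha
        for i in range(n):
            if st[i] == 1 or st[i] == 4:
                total += dwell_rate
            else:
                total += v
        dt = np.random.exponential(1.0 / total)
        occ_int += n * dt
        occ2_int += n * n * dt
        t += dt
        if t > max_time:
            status = STATUS_TIME_EXCEEDED
            break

        u = np.random.random() * total
        if u < alpha:
            # entry attempt at site 1 (null event if the entrance is blocked)
            if n == 0 or pos[n - 1] >= 1 + footprint:
                if n == _CAPACITY:
                    status = STATUS_OVERFLOW
                    break
                pos[n] = 1
                st[n] = 1 if uorf1_start == 1 else 0
                entry_t[n] = t
                n += 1
                entered += 1
            continue

        # pick the scanner owning the event
        u -= alpha
        i = 0
        while i < n:
            r = dwell_rate if (st[i] == 1 or st[i] == 4) else v
            if u < r:
                break
            u -= r
            i += 1
        if i == n:  # numerical edge of the cumulative sum
            i = n - 1

        remove = False
        fate = -1
        if st[i] == 1:
            # uORF1 termination: resume at the stop codon with prob eta
            if i > 0 and pos[i - 1] - uorf1_stop < footprint:
                continue  # downstream neighbour blocks the resume site
            if np.random.random() < eta:
                pos[i] = uorf1_stop
                st[i] = 2
            else:
                remove = True
                fate = 0
        elif st[i] == 4:
            remove = True
            fate = 1
        else:
            # hop +1 nt under exclusion
            if i > 0 and pos[i - 1] - pos[i] < footprint + 1:
                continue
            pos[i] += 1
            if st[i] == 2 and np.random.random() < p_bind:
                st[i] = 3
            p = pos[i]
            if st[i] == 0 and p == uorf1_start:
                st[i] = 1
            elif st[i] == 3 and p == uorf4_start:
                st[i] = 4
            elif p == gcn4_start:
                remove = True
                fate = 2 if st[i] == 3 else 3

        if remove:
            counts[fate] += 1
            completed += 1
            resid_sum += t - entry_t[i]
            for j in range(i, n - 1):
                pos[j] = pos[j + 1]
                st[j] = st[j + 1]
                entry_t[j] = entry_t[j + 1]
            n -= 1

    return counts, occ_int, occ2_int, t, completed, entered, resid_sum, status
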