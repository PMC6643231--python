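"""Numba kernels for the Gillespie direct method.

Each kernel seeds numba's internal Mersenne Twister once and then consumes
exactly two uniforms per reaction event: one for the exponential waiting
time, one for reaction selection. Immigration events reuse the selection
uniform (rescaled within the immigration slice of the total rate) to pick
the colonizing taxon, so the two-uniform accounting holds for community
runs as well. The rate laws here must stay in lockstep with
:mod:`matecomm.rates`; cross-checks live in the test suite.

Event-kind codes used in community logs: 0=birth, 1=death, 2=immigration,
3=extinction (a death that emptied the population also emits 3).
"""

import numpy as np
from numba import njit

KIND_BIRTH = 0
KIND_DEATH = 1
KIND_IMMIGRATION = 2
KIND_EXTINCTION = 3

# recompute running rate totals this often to cancel float drift
_RESYNC = 1 << 20


@njit(cache=True)
def population_kernel(b, d, c, n0, t_max, seed, record):
    """Single-population birth-death chain.

    c <= 0 means asexual; c > 0 is the mate-encounter coefficient.
    Returns (times, sizes, final_time, censored). times/sizes include the
    initial state and are length-1 when record=False.
    """
    np.random.seed(seed)
    cap = 1024
    times = np.empty(cap, np.float64)
    sizes = np.empty(cap, np.int64)
    times[0] = 0.0
    sizes[0] = n0
    m = 1
    n = n0
    t = 0.0
    censored = False
    while n > 0:
        br = b * n
        if c > 0.0:
            br *= -np.expm1(-c * n)
        dr = d * n * n
        tot = br + dr
        u1 = np.random.random()
        u2 = np.random.random()
        t_next = t - np.log(1.0 - u1) / tot
        if t_next > t_max:
            t = t_max
            censored = True
            break
        t = t_next
        if u2 * tot < br:
            n += 1
        else:
            n -= 1
        if record:
            if m == cap:
                cap *= 2
                nt = np.empty(cap, np.float64)
                nt[:m] = times[:m]
                times = nt
                ns = np.empty(cap, np.int64)
                ns[:m] = sizes[:m]
                sizes = ns
            times[m] = t
            sizes[m] = n
            m += 1
    return times[:m].copy(), sizes[:m].copy(), t, censored


@njit(cache=True)
def extinction_times_kernel(b, d, c, n0, t_max, seeds):
    """Absorption times for a batch of independent replicate populations."""
    n_reps = seeds.shape[0]
    out = np.empty(n_reps, np.float64)
    censored = np.zeros(n_reps, np.bool_)
    for r in range(n_reps):
        np.random.seed(seeds[r])
        n = n0
        t = 0.0
        while n > 0:
            br = b * n
            if c > 0.0:
                br *= -np.expm1(-c * n)
            dr = d * n * n
            tot = br + dr
            u1 = np.random.random()
            u2 = np.random.random()
            t_next = t - np.log(1.0 - u1) / tot
            if t_next > t_max:
                t = t_max
                censored[r] = True
                break
            t = t_next
            if u2 * tot < br:
                n += 1
            else:
                n -= 1
        out[r] = t
    return out, censored


@njit(cache=True)
def _grow_f8(arr, m):
    out = np.empty(arr.shape[0] * 2, np.float64)
    out[:m] = arr[:m]
    return out


@njit(cache=True)
def _grow_i4(arr, m):
    out = np.empty(arr.shape[0] * 2, np.int32)
    out[:m] = arr[:m]
    return out


@njit(cache=True)
def _grow_i1(arr, m):
    out = np.empty(arr.shape[0] * 2, np.int8)
    out[:m] = arr[:m]
    return out


@njit(cache=True)
def community_kernel(
    b_vec,
    d_vec,
    c_vec,
    i_rate,
    colonize_size,
    burn_in,
    interval,
    n_samples,
    seed,
    record_full,
):
    """Coupled multi-taxon reaction network with immigration.

    Per-taxon birth and death reactions plus one aggregate immigration
    reaction whose rate is (pool - diversity) * i_rate; an immigration sets
    a uniformly chosen absent taxon to colonize_size. Abundance snapshots
    are taken every `interval` events after `burn_in` events.

    Returns (samples, sample_times, sample_events, n_sampled,
             log_times, log_taxa, log_kinds, n_log, stalled,
             total_events, final_time).
    """
    pool = b_vec.shape[0]
    np.random.seed(seed)

    n = np.zeros(pool, np.int64)
    br = np.zeros(pool, np.float64)
    dr = np.zeros(pool, np.float64)
    diversity = 0
    sum_react = 0.0

    samples = np.zeros((n_samples, pool), np.int64)
    sample_times = np.zeros(n_samples, np.float64)
    sample_events = np.zeros(n_samples, np.int64)
    n_sampled = 0

    cap = 4096
    log_t = np.empty(cap, np.float64)
    log_taxon = np.empty(cap, np.int32)
    log_kind = np.empty(cap, np.int8)
    n_log = 0

    t = 0.0
    events = 0
    target_events = burn_in + interval * n_samples
    stalled = False

    while events < target_events:
        imm = (pool - diversity) * i_rate
        total = sum_react + imm
        if total <= 0.0:
            stalled = True
            break
        u1 = np.random.random()
        u2 = np.random.random()
        t -= np.log(1.0 - u1) / total
        r = u2 * total

        if n_log + 2 > cap:
            log_t = _grow_f8(log_t, n_log)
            log_taxon = _grow_i4(log_taxon, n_log)
            log_kind = _grow_i1(log_kind, n_log)
            cap = log_t.shape[0]

        if r < imm:
            # immigration: pick the j-th currently absent taxon, j uniform
            # via the rescaled selection uniform (no extra draw)
            n_absent = pool - diversity
            j = int(r / imm * n_absent)
            if j >= n_absent:
                j = n_absent - 1
            k = -1
            seen = 0
            for kk in range(pool):
                if n[kk] == 0:
                    if seen == j:
                        k = kk
                        break
                    seen += 1
            n[k] = colonize_size
            new_br = b_vec[k] * n[k]
            if c_vec[k] > 0.0:
                new_br *= -np.expm1(-c_vec[k] * n[k])
            new_dr = d_vec[k] * n[k] * n[k]
            sum_react += new_br + new_dr
            br[k] = new_br
            dr[k] = new_dr
            diversity += 1
            log_t[n_log] = t
            log_taxon[n_log] = k
            log_kind[n_log] = KIND_IMMIGRATION
            n_log += 1
        else:
            r -= imm
            k = -1
            is_birth = False
            acc = 0.0
            for kk in range(pool):
                acc += br[kk]
                if r < acc:
                    k = kk
                    is_birth = True
                    break
            if k < 0:
                for kk in range(pool):
                    acc += dr[kk]
                    if r < acc:
                        k = kk
                        break
            if k < 0:
                # float drift pushed r past the end: fire the largest death
                best = -1.0
                for kk in range(pool):
                    if dr[kk] > best:
                        best = dr[kk]
                        k = kk
            if is_birth:
                n[k] += 1
            else:
                n[k] -= 1
            old = br[k] + dr[k]
            new_br = b_vec[k] * n[k]
            if c_vec[k] > 0.0 and n[k] > 0:
                new_br *= -np.expm1(-c_vec[k] * n[k])
            new_dr = d_vec[k] * n[k] * n[k]
            br[k] = new_br
            dr[k] = new_dr
            sum_react += new_br + new_dr - old
            if record_full:
                log_t[n_log] = t
                log_taxon[n_log] = k
                log_kind[n_log] = KIND_BIRTH if is_birth else KIND_DEATH
                n_log += 1
            if not is_birth and n[k] == 0:
                diversity -= 1
                log_t[n_log] = t
                log_taxon[n_log] = k
                log_kind[n_log] = KIND_EXTINCTION
                n_log += 1

        events += 1
        if events % _RESYNC == 0:
            s = 0.0
            for kk in range(pool):
                s += br[kk] + dr[kk]
            sum_react = s
        if events > burn_in and (events - burn_in) % interval == 0:
            for kk in range(pool):
                samples[n_sampled, kk] = n[kk]
            sample_times[n_sampled] = t
            sample_events[n_sampled] = events
            n_sampled += 1

    return (
        samples,
        sample_times,
        sample_events,
        n_sampled,
        log_t[:n_log].copy(),
        log_taxon[:n_log].copy(),
        log_kind[:n_log].copy(),
        n_log,
        stalled,
        events,
        t,
    )
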