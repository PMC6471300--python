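"""Numba kernel for the overdamped-Langevin / well-tempered metadynamics loop.

The inner loop is sequential (each step depends on the last), so it is JIT
compiled.  Two tabulation tricks keep the per-step cost O(1):

* the axial potential gradient is pre-tabulated on a fine grid and linearly
  interpolated;
* the metadynamics bias and its gradient are accumulated on a second fine
  grid as hills are deposited (a gridded-bias cache).  The grid spacing is a
  small fraction of the hill width, so cached energies agree with the exact
  Gaussian summation to well below 1e-6 kcal/mol.

The kernel supports an arbitrary (small) number of CVs: the axial profile
acts on coordinate 0, a harmonic confinement of stiffness ``radial_k`` acts
on the remaining coordinates, the bias acts on coordinate 0 only, and
half-harmonic walls may act on any coordinate.
"""

import numpy as np
from numba import njit

#: status codes returned by the kernel
OK = 0
DIVERGED = 1


@njit(cache=True)
def run_langevin(
    x0,                # (d,) initial CV values
    n_steps,           # int
    dt,                # fs
    mobility,          # D / kBT, Å²/(fs·kcal/mol)
    noise_scale,       # sqrt(2 D dt), Å
    tab_lo, tab_h, u_grad_tab,   # axial potential gradient table
    radial_k,          # harmonic stiffness on coords 1..d-1
    wall_k, wall_lo, wall_hi,    # (d,) half-harmonic wall parameters (k=0: off)
    biased,            # bool: deposit hills
    hill_h0, hill_delta, kb_delta_t, tau_steps,
    bias_lo, bias_h, bias_val, bias_grad,   # gridded bias cache (modified)
    sanity_bound,      # abort when |x[0]| exceeds this
    stride,            # save every stride-th step
    traj_out,          # (n_saved, d) output
    hill_t, hill_c, hill_height,  # (max_hills,) output
    seed,
):
    np.random.seed(seed)
    d = x0.shape[0]
    x = x0.copy()
    n_hills = 0
    n_saved = 0
    nsup = int(8.0 * hill_delta / bias_h) + 1  # bias-grid support half-width
    inv_bias_h = 1.0 / bias_h
    inv_tab_h = 1.0 / tab_h
    n_tab = u_grad_tab.shape[0]
    n_bias = bias_val.shape[0]
    inv_2d2 = 1.0 / (2.0 * hill_delta * hill_delta)

    for step in range(n_steps):
        # --- hill deposition every tau_steps, starting after the first period
        if biased and step > 0 and step % tau_steps == 0:
            # bias at the current CV, from the cache
            fb = (x[0] - bias_lo) * inv_bias_h
            jb = int(np.floor(fb))
            if jb < 0:
                jb = 0
            if jb > n_bias - 2:
                jb = n_bias - 2
            wb = fb - jb
            vb = bias_val[jb] * (1.0 - wb) + bias_val[jb + 1] * wb
            if vb < 0.0:
                vb = 0.0
            h = hill_h0 * np.exp(-vb / kb_delta_t)
            hill_t[n_hills] = step * dt
            hill_c[n_hills] = x[0]
            hill_height[n_hills] = h
            n_hills += 1
            # accumulate the hill on the cache over its support
            jc = int(np.floor((x[0] - bias_lo) * inv_bias_h))
            j0 = jc - nsup
            j1 = jc + nsup + 1
            if j0 < 0:
                j0 = 0
            if j1 > n_bias:
                j1 = n_bias
            for j in range(j0, j1):
                s = bias_lo + j * bias_h
                ds = s - x[0]
                g = h * np.exp(-ds * ds * inv_2d2)
                bias_val[j] += g
                bias_grad[j] += -ds / (hill_delta * hill_delta) * g

        # --- force on coordinate 0: tabulated potential + bias + wall
        ft = (x[0] - tab_lo) * inv_tab_h
        jt = int(np.floor(ft))
        if jt < 0 or jt > n_tab - 2:
            return n_hills, n_saved, DIVERGED, step
        wt = ft - jt
        g0 = u_grad_tab[jt] * (1.0 - wt) + u_grad_tab[jt + 1] * wt
        fb = (x[0] - bias_lo) * inv_bias_h
        jb = int(np.floor(fb))
        if 0 <= jb <= n_bias - 2:
            wb = fb - jb
            g0 += bias_grad[jb] * (1.0 - wb) + bias_grad[jb + 1] * wb
        if wall_k[0] > 0.0:
            if x[0] > wall_hi[0]:
                g0 += wall_k[0] * (x[0] - wall_hi[0])
            elif x[0] < wall_lo[0]:
                g0 += wall_k[0] * (x[0] - wall_lo[0])
        x[0] += -mobility * g0 * dt + noise_scale * np.random.normal()

        # --- remaining coordinates: radial harmonic + optional walls
        for i in range(1, d):
            gi = radial_k * x[i]
            if wall_k[i] > 0.0:
                if x[i] > wall_hi[i]:
                    gi += wall_k[i] * (x[i] - wall_hi[i])
                elif x[i] < wall_lo[i]:
                    gi += wall_k[i] * (x[i] - wall_lo[i])
            x[i] += -mobility * gi * dt + noise_scale * np.random.normal()

        if abs(x[0]) > sanity_bound:
            return n_hills, n_saved, DIVERGED, step

        if (step + 1) % stride == 0:
            for i in range(d):
                traj_out[n_saved, i] = x[i]
            n_saved += 1

    return n_hills, n_saved, OK, n_steps
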