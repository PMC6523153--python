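"""Optional numba acceleration.

Numerical kernels (the BayesB sweep, the PCIT triple loop) are written in
nopython-compatible style and jitted when numba is importable; otherwise the
same functions run as plain Python.  Chains are reproducible for a fixed
seed and backend.
"""

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap
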