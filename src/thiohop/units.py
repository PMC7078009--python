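"""Physical constants and unit conversions.

Atomic units (hbar = m_e = e = a0 = 1) are used internally everywhere;
interfaces speak eV, fs, Angstrom and cm^-1.  All conversion factors live
here and nowhere else.
"""

# CODATA 2018
EV_PER_HARTREE = 27.211386245988
HARTREE_PER_EV = 1.0 / EV_PER_HARTREE

FS_PER_AUT = 0.02418884326586  # atomic time unit in fs
AUT_PER_FS = 1.0 / FS_PER_AUT

ANGSTROM_PER_BOHR = 0.529177210903
BOHR_PER_ANGSTROM = 1.0 / ANGSTROM_PER_BOHR

# cm^-1 -> Hartree (via h*c)
HARTREE_PER_CM1 = 4.556335252912e-6
CM1_PER_HARTREE = 1.0 / HARTREE_PER_CM1

# atomic mass unit (Dalton) in electron masses
AMU_TO_AU = 1822.888486209


def ev_to_au(e):
    return e * HARTREE_PER_EV


def au_to_ev(e):
    return e * EV_PER_HARTREE


def fs_to_au(t):
    return t * AUT_PER_FS


def au_to_fs(t):
    return t * FS_PER_AUT


def cm1_to_au(w):
    return w * HARTREE_PER_CM1


def au_to_cm1(w):
    return w * CM1_PER_HARTREE
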