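# Default parameter bounds (uniform search ranges) for model calibration.
# One list [lower, upper] per parameter, in each model's parameter order.
# These are package defaults chosen to bracket plausible boreal/temperate
# values; override any entry through FitConfig.bounds.
spring:
  LIN:
    a: [0, 250]
    b: [-30, 30]
  TT:
    t0: [1, 120]
    T_base: [-5, 15]
    F_star: [1, 500]
  TTs:
    t0: [1, 120]
    b_f: [0.05, 5]
    c_f: [-5, 20]
    F_star: [1, 200]
  PTT:
    t0: [1, 120]
    T_base: [-5, 15]
    F_star: [1, 300]
  PTTs:
    t0: [1, 120]
    b_f: [0.05, 5]
    c_f: [-5, 20]
    F_star: [1, 150]
  M1:
    t0: [1, 120]
    T_base: [-5, 15]
    k: [0.1, 5]
    F_star: [1, 500]
  M1s:
    t0: [1, 120]
    b_f: [0.05, 5]
    c_f: [-5, 20]
    k: [0.1, 5]
    F_star: [1, 300]
  AT:
    t0: [1, 120]
    T_base: [-5, 15]
    a: [1, 1000]
    b: [1, 5000]
    c: [-2, -0.001]
  SQ:
    t0: [1, 150]
    t0_chill: [-121, 30]
    T_base: [-5, 15]
    T_min: [-15, 4.9]
    T_opt: [-5, 12]
    T_max: [0, 20]
    C_star: [0.1, 150]
    F_star: [1, 500]
  SQb:
    t0: [1, 150]
    t0_chill: [-121, 30]
    T_base: [-5, 15]
    a_c: [0.001, 2]
    b_c: [-2, 2]
    c_c: [-10, 15]
    C_star: [0.1, 150]
    F_star: [1, 500]
  SM1:
    t0: [1, 150]
    t0_chill: [-121, 30]
    T_base: [-5, 15]
    k: [0.1, 5]
    T_min: [-15, 4.9]
    T_opt: [-5, 12]
    T_max: [0, 20]
    C_star: [0.1, 150]
    F_star: [1, 500]
  SM1b:
    t0: [1, 150]
    t0_chill: [-121, 30]
    T_base: [-5, 15]
    k: [0.1, 5]
    a_c: [0.001, 2]
    b_c: [-2, 2]
    c_c: [-10, 15]
    C_star: [0.1, 150]
    F_star: [1, 500]
  PA:
    t0: [1, 150]
    t0_chill: [-121, 30]
    T_base: [-5, 15]
    T_min: [-15, 4.9]
    T_opt: [-5, 12]
    T_max: [0, 20]
    C_ini: [0, 100]
    C_star: [0.1, 150]
    F_star: [1, 500]
  PAb:
    t0: [1, 150]
    t0_chill: [-121, 30]
    T_base: [-5, 15]
    a_c: [0.001, 2]
    b_c: [-2, 2]
    c_c: [-10, 15]
    C_ini: [0, 100]
    C_star: [0.1, 150]
    F_star: [1, 500]
  PM1:
    t0: [1, 150]
    t0_chill: [-121, 30]
    T_base: [-5, 15]
    k: [0.1, 5]
    T_min: [-15, 4.9]
    T_opt: [-5, 12]
    T_max: [0, 20]
    C_ini: [0, 100]
    C_star: [0.1, 150]
    F_star: [1, 500]
  PM1b:
    t0: [1, 150]
    t0_chill: [-121, 30]
    T_base: [-5, 15]
    k: [0.1, 5]
    a_c: [0.001, 2]
    b_c: [-2, 2]
    c_c: [-10, 15]
    C_ini: [0, 100]
    C_star: [0.1, 150]
    F_star: [1, 500]
  UM1:
    t0: [-121, 60]
    a_c: [0.001, 2]
    b_c: [-2, 2]
    c_c: [-10, 15]
    b_f: [0.05, 5]
    c_f: [-5, 20]
    k: [0.1, 5]
    w: [1, 500]
    z: [0, 2]
  SGSI:
    t0: [1, 120]
    T_min: [-10, 10]
    T_max: [0.1, 30]
    V_min: [0, 2]
    V_max: [0.5, 6]
    L_min: [6, 14]
    L_max: [10, 20]
    k: [0.1, 5]
    threshold: [0.01, 0.99]
  AGSI:
    t0: [1, 120]
    T_min: [-10, 10]
    T_max: [0.1, 30]
    V_min: [0, 2]
    V_max: [0.5, 6]
    L_min: [6, 14]
    L_max: [10, 20]
    k: [0.1, 5]
    F_star: [1, 200]
autumn:
  CDD:
    t0: [180, 320]
    T_base: [5, 30]
    F_star: [1, 1000]
  CDDCO2:
    t0: [180, 320]
    T_base: [5, 30]
    F_star: [1, 1000]
    c_co2: [0, 2]
  CDDs:
    t0: [180, 320]
    b_s: [0.05, 5]
    c_s: [-5, 25]
    F_star: [1, 200]
  CDDsCO2:
    t0: [180, 320]
    b_s: [0.05, 5]
    c_s: [-5, 25]
    F_star: [1, 200]
    c_co2: [0, 0.5]
  CDDP:
    t0: [180, 320]
    T_base: [5, 30]
    F_star: [1, 500]
  CDDPCO2:
    t0: [180, 320]
    T_base: [5, 30]
    F_star: [1, 500]
    c_co2: [0, 1]
  CDDM:
    t0: [180, 320]
    T_base: [5, 30]
    m: [-0.05, 0.05]
    F_star: [1, 1000]
  CDDMCO2:
    t0: [180, 320]
    T_base: [5, 30]
    m: [-0.05, 0.05]
    F_star: [1, 1000]
    c_co2: [0, 2]
  PPM:
    L_crit: [10, 20]
    m: [-0.05, 0.05]
    F_star: [1, 500]
  PPMCO2:
    L_crit: [10, 20]
    m: [-0.05, 0.05]
    F_star: [1, 500]
    c_co2: [0, 1]
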