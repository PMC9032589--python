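activity_name,gx,gy,gz,f0_hz,amp_g,noise_g,met_mu,met_sigma
COMPUTER WORK,0.25,0.90,0.35,0.10,0.010,0.010,1.30,0.15
TV WATCHING,0.85,0.35,0.40,0.00,0.000,0.008,1.10,0.10
STANDING STILL,0.10,0.25,0.96,0.00,0.004,0.008,1.30,0.15
STAIR DESCENT,0.30,0.80,0.52,1.50,0.300,0.050,3.80,0.35
STAIR ASCENT,0.32,0.78,0.54,1.40,0.300,0.050,4.50,0.40
RAPID WALK,0.35,0.75,0.56,2.00,0.350,0.050,4.20,0.35
LEISURE WALK,0.35,0.76,0.55,1.70,0.250,0.050,3.20,0.30
WALKING AT RPE 5,0.34,0.77,0.55,1.90,0.300,0.050,4.00,0.35
WALKING AT RPE 1,0.36,0.75,0.56,1.60,0.220,0.050,3.00,0.30
STRENGTH EXERCISE CHEST PRESS,0.52,0.60,0.61,0.80,0.130,0.050,2.40,0.30
STRENGTH EXERCISE LEG CURL,0.55,0.58,0.60,0.75,0.100,0.050,2.20,0.25
STRETCHING YOGA,0.53,0.61,0.59,0.70,0.120,0.050,1.80,0.20
STRENGTH EXERCISE LEG EXTENSION,0.54,0.59,0.60,0.85,0.110,0.050,2.30,0.25
WASHING WINDOWS,0.40,0.70,0.59,1.10,0.280,0.060,3.20,0.30
DIGGING,0.45,0.65,0.61,0.90,0.300,0.070,4.30,0.40
IRONING,0.50,0.62,0.60,0.90,0.140,0.050,2.10,0.25
MOPPING,0.42,0.68,0.60,1.00,0.250,0.060,3.40,0.30
WASHING DISHES,0.52,0.60,0.61,0.80,0.120,0.050,1.90,0.20
REPLACING SHEETS ON A BED,0.44,0.66,0.61,0.80,0.200,0.060,3.10,0.30
HEAVY LIFTING,0.48,0.62,0.62,0.70,0.270,0.070,4.00,0.40
PERSONAL CARE,0.54,0.58,0.61,0.85,0.110,0.050,2.00,0.20
UNLOADING STORING DISHES,0.50,0.61,0.61,0.90,0.130,0.050,2.40,0.25
SWEEPING,0.41,0.69,0.60,1.10,0.220,0.060,3.20,0.30
VACUUMING,0.43,0.67,0.60,1.00,0.200,0.060,3.30,0.30
LIGHT GARDENING,0.46,0.64,0.62,0.90,0.180,0.060,3.10,0.30
SHOPPING,0.53,0.59,0.61,0.75,0.100,0.050,2.20,0.25
LIGHT HOME MAINTENANCE,0.47,0.63,0.62,0.85,0.200,0.060,3.00,0.30
PREPARE SERVE MEAL,0.55,0.57,0.61,0.80,0.120,0.050,2.00,0.20
LAUNDRY WASHING,0.51,0.60,0.62,0.85,0.110,0.050,2.10,0.25
YARD WORK,0.45,0.64,0.62,0.95,0.240,0.070,3.80,0.35
STRAIGHTENING UP DUSTING,0.49,0.61,0.62,1.05,0.180,0.060,3.00,0.30
TRASH REMOVAL,0.46,0.63,0.63,0.90,0.200,0.060,3.10,0.30
DRESSING,0.56,0.56,0.61,0.70,0.120,0.050,2.30,0.25
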