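activity_name,type_category,intensity_category
COMPUTER WORK,Sedentary,Low
TV WATCHING,Sedentary,Low
STANDING STILL,Sedentary,Low
STAIR DESCENT,Locomotion,Moderate
STAIR ASCENT,Locomotion,Moderate
RAPID WALK,Locomotion,Moderate
LEISURE WALK,Locomotion,Moderate
WALKING AT RPE 5,Locomotion,Moderate
WALKING AT RPE 1,Locomotion,Moderate
STRENGTH EXERCISE CHEST PRESS,SFE,Light
STRENGTH EXERCISE LEG CURL,SFE,Light
STRETCHING YOGA,SFE,Light
STRENGTH EXERCISE LEG EXTENSION,SFE,Light
WASHING WINDOWS,Lifestyle,Moderate
DIGGING,Lifestyle,Moderate
IRONING,Lifestyle,Light
MOPPING,Lifestyle,Moderate
WASHING DISHES,Lifestyle,Light
REPLACING SHEETS ON A BED,Lifestyle,Moderate
HEAVY LIFTING,Lifestyle,Moderate
PERSONAL CARE,Lifestyle,Light
UNLOADING STORING DISHES,Lifestyle,Light
SWEEPING,Lifestyle,Moderate
VACUUMING,Lifestyle,Moderate
LIGHT GARDENING,Lifestyle,Moderate
SHOPPING,Lifestyle,Light
LIGHT HOME MAINTENANCE,Lifestyle,Moderate
PREPARE SERVE MEAL,Lifestyle,Light
LAUNDRY WASHING,Lifestyle,Light
YARD WORK,Lifestyle,Moderate
STRAIGHTENING UP DUSTING,Lifestyle,Moderate
TRASH REMOVAL,Lifestyle,Moderate
DRESSING,Lifestyle,Light
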