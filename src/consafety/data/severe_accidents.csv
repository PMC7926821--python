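date,region,accident_type,location,deaths,serious_injury,cause
2010-08-16,Jilin,lifting_injury,,11,false,"Elevator drive system ran overloaded for a long time; the motor brake failed and the construction elevator cage fell."
2011-10-08,Liaoning,collapse,,13,false,"Support-system rods were dismantled while concrete pouring continued; the scaffold lost stability and the basement roof collapsed."
2012-09-18,Hubei,fall_from_height,,19,false,"Force-bearing bolt nuts on the guide rail fell off and the cage tipped over; the safety device was damaged and the operator unlicensed."
2014-12-29,Beijing,collapse,,10,false,"Materials and split heads were not arranged per plan; the split heads and steel bars formed no complete structure and the foundation slab collapsed."
2018-02-07,Guangdong,collapse,,12,false,"Shield-tunnel end sealing broke under water and soil pressure; mud and sand rushed into the tunnel and the evacuation was slow."
2019-04-25,Hebei,fall_from_height,,11,false,"Two connection bolts of the construction lift were not installed; the lift was used without inspection or acceptance checks."
2019-05-16,Shanghai,collapse,,12,false,"A load-bearing wall with insufficient capacity was left unsupported during construction and part of the factory collapsed in a chain reaction."
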