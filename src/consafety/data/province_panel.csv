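region,accidents,deaths,rate_production,rate_staff,cluster_absolute,cluster_relative
Beijing,192,226,20.66,58.25,3,3
Tianjin,136,154,40.74,42.42,3,3
Hebei,90,140,24.48,14.77,3,3
Shanxi,61,95,23.17,13.65,3,3
Inner Mongolia,125,174,162.62,70.45,3,2
Liaoning,118,167,45.88,28.16,3,3
Jilin,179,214,105.42,68.37,3,2
Heilongjiang,204,234,191.80,97.10,3,2
Shanghai,268,305,42.90,44.08,2,3
Jiangsu,665,749,24.20,10.41,1,3
Zhejiang,354,401,19.40,6.47,2,3
Anhui,318,377,47.60,20.36,2,3
Fujian,190,217,19.02,5.53,3,3
Jiangxi,174,214,31.15,14.87,3,3
Shandong,152,226,18.93,7.84,3,3
Henan,145,213,19.02,8.71,3,3
Hubei,232,307,20.22,15.06,2,3
Hunan,167,204,21.23,8.79,3,3
Guangdong,363,452,32.61,19.40,2,3
Guangxi,213,239,54.32,20.13,3,3
Hainan,82,91,252.78,151.67,3,1
Chongqing,366,390,53.13,22.58,2,3
Sichuan,292,341,24.95,9.72,2,3
Guizhou,148,208,62.09,27.62,3,3
Yunnan,233,271,50.84,22.99,2,3
Xizang,10,20,111.11,46.51,3,2
Shaanxi,72,96,13.69,7.11,3,3
Gansu,153,184,101.66,38.74,3,2
Qinghai,101,115,261.36,136.90,3,1
Ningxia,65,81,142.11,87.10,3,2
Xinjiang,160,191,89.67,54.73,3,2
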